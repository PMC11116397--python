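"""Skeletons, cristae counting and the three-class morphology rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.measure import label as cc_label

from conftest import acquire_scene, sted_settings
from mitograph.errors import EstimationError, ParameterError
from mitograph.morphometry import (
    ClassificationRule,
    MitochondrionRecord,
    classify_mitochondrion,
    count_cristae,
    skeletonize_component,
    summarize_population,
)
from mitograph.scene import build_tubule_grid
from mitograph.segmentation import SegmentationConfig, segment_cristae, segment_mitochondria


class TestClassificationRule:
    @pytest.mark.parametrize(
        "length,count,expected",
        [
            (6.0, 10, "III"),    # long: length branch of the III rule
            (1.0, 3, "I"),       # short and few cristae
            (3.0, 4, "II"),      # intermediate length
            (1.0, 13, "III"),    # many cristae override a short length
            (2.5, 3, "II"),      # boundary: 2.5 um belongs to the II interval
            (5.0, 3, "II"),      # boundary: 5 um still II
            (1.0, 6, "II"),      # boundary: 6 cristae reaches II
            (1.0, 12, "II"),     # boundary: 12 cristae still II
            (5.000001, 0, "III"),
            (0.0, 0, "I"),
        ],
    )
    def test_examples_and_boundaries(self, length, count, expected):
        assert classify_mitochondrion(length, count) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ParameterError):
            classify_mitochondrion(-1.0, 3)
        with pytest.raises(ParameterError):
            classify_mitochondrion(1.0, -1)

    @settings(derandomize=True, max_examples=300)
    @given(
        length=st.one_of(
            st.floats(0.0, 10.0),
            st.sampled_from([2.5, 5.0, 2.4999, 5.0001]),
        ),
        count=st.integers(0, 30),
    )
    def test_partition_is_total_and_exclusive(self, length, count):
        # every (length, count) maps to exactly one class, and the class
        # agrees with the direct reading of the thresholds
        cls = classify_mitochondrion(length, count)
        in_iii = length > 5.0 or count > 12
        in_ii = not in_iii and (length >= 2.5 or count >= 6)
        expected = "III" if in_iii else ("II" if in_ii else "I")
        assert cls == expected

    def test_inconsistent_rule_rejected(self):
        with pytest.raises(ParameterError):
            ClassificationRule(length_low_um=5.0, length_high_um=2.5)


class TestSkeletonize:
    def test_thin_bar_length_and_landmarks(self):
        mask = np.zeros((11, 120), dtype=np.int32)
        mask[5, 10:110] = 1  # 100 px at 20 nm spans 99 steps = 1.98 um
        sg = skeletonize_component(mask, 1, 20.0)
        assert sg.total_length_um == pytest.approx(2.0, abs=0.02)
        assert sg.n_tips == 2
        assert sg.n_branch_points == 0

    def test_y_shape_has_three_tips_one_branch_point(self):
        from scipy.ndimage import binary_dilation

        m = np.zeros((200, 200), dtype=bool)
        m[100, 20:180] = True
        for i in range(60):
            m[100 - i, 100 + i] = True
        m = binary_dilation(m, iterations=3)
        sg = skeletonize_component(m.astype(np.int32), 1, 20.0)
        assert sg.n_tips == 3
        assert sg.n_branch_points == 1

    def test_ring_has_no_landmarks_and_full_circumference(self):
        yy, xx = np.indices((200, 200))
        r = np.hypot(yy - 100, xx - 100)
        ring = ((r > 40) & (r < 50)).astype(np.int32)
        sg = skeletonize_component(ring, 1, 20.0)
        assert sg.n_tips == 0
        assert sg.n_branch_points == 0
        assert sg.total_length_um == pytest.approx(2 * np.pi * 45 * 0.02, rel=0.08)

    def test_missing_label_raises_lookup_error(self):
        with pytest.raises(LookupError):
            skeletonize_component(np.zeros((10, 10), dtype=np.int32), 3, 20.0)

    def test_rendered_tubule_length_recovered_within_5pct(self):
        # full chain: render -> segment -> close -> skeletonize
        cfg = SegmentationConfig()
        for seed, length in ((31, 3.0), (32, 5.0)):
            scene = build_tubule_grid(1, length_um=length, seed=seed)[0]
            img = acquire_scene(scene, "IM", sted_settings(), seed=seed)
            _, mask = segment_cristae(img, cfg)
            labels = segment_mitochondria(mask, cfg, 20.0)
            sg = skeletonize_component(labels, 1, 20.0)
            measured = sg.total_length_um - 0.09 * sg.n_tips  # halo correction
            assert measured == pytest.approx(length, rel=0.05)


class TestCountCristae:
    def test_counts_match_generator_truth_at_high_snr(self):
        # cluster-spaced cristae (>= 0.3 um apart) are individually
        # resolvable at a 40 nm PSF, so component counting recovers truth
        import pandas as pd

        from mitograph.scene import build_population_scenes

        samples = pd.DataFrame(
            {"length_um": [3.2, 4.1, 2.4], "n_cristae": [8, 11, 6],
             "true_class": ["II", "II", "II"]}
        )
        scene = build_population_scenes(samples, seed=17)[0]
        img = acquire_scene(scene, "IM", sted_settings(), seed=34)
        cfg = SegmentationConfig(closing_radius_nm=350.0)
        _, mask = segment_cristae(img, cfg)
        labels = segment_mitochondria(mask, cfg, 20.0)
        assert labels.max() == 3
        for lab in range(1, 4):
            # match the measured component to its truth row by height
            ys = np.mean(np.argwhere(labels == lab)[:, 0]) * 0.02
            comp = scene.components[int(round((ys - 1.2) / 1.8))]
            measured = count_cristae(lab, mask, labels)
            assert abs(measured - comp.n_cristae) <= 1

    def test_empty_mask_counts_zero(self):
        labels = np.ones((32, 32), dtype=np.int32)
        assert count_cristae(1, np.zeros((32, 32), dtype=bool), labels) == 0

    def test_counts_partition_across_mitochondria(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:8, 5:8] = True
        mask[5:8, 30:33] = True
        mask[30:33, 5:8] = True
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[:20, :20] = 1
        labels[:20, 20:] = 2
        labels[20:, :] = 3
        counts = [count_cristae(lab, mask, labels) for lab in (1, 2, 3)]
        assert counts == [1, 1, 1]
        assert sum(counts) == cc_label(mask, connectivity=2).max()


class TestSummarizePopulation:
    @staticmethod
    def record(label, length, count):
        return MitochondrionRecord(
            label=label, length_um=length, n_cristae=count,
            morph_class=classify_mitochondrion(length, count),
            mito_area_um2=1.0, cristae_area_um2=0.5,
        )

    def test_pure_class_one_population(self):
        recs = [self.record(i, 1.0, 2) for i in range(5)]
        props, table = summarize_population(recs)
        assert props == {"I": 1.0, "II": 0.0, "III": 0.0}
        assert len(table) == 5

    def test_proportions_invariant_under_order(self):
        recs = [self.record(i, l, c) for i, (l, c) in
                enumerate([(1, 2), (3, 4), (7, 20), (1, 13), (2.5, 5)])]
        p1, _ = summarize_population(recs)
        p2, _ = summarize_population(list(reversed(recs)))
        assert p1 == p2

    def test_empty_population_is_an_error(self):
        with pytest.raises(EstimationError):
            summarize_population([])
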