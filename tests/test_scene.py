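"""Synthetic-scene generator: geometry, nucleoid laws, population mixtures."""

import numpy as np
import pytest
from scipy import stats

from mitograph.errors import ParameterError
from mitograph.morphometry import classify_mitochondrion
from mitograph.scene import (
    GroundTruthScene,
    NucleoidPlacement,
    SceneParams,
    build_tubule_grid,
    generate_network,
    rasterize_cristae,
    render_density,
    sample_morphology_population,
    sample_nucleoids,
)
from mitograph.spatial import fraction_below, nearest_distances

TIP_RATE = 1.7470  # -ln(0.35)/0.6, the rate matching 65% of distances < 0.6 um


class TestGenerateNetwork:
    def test_same_seed_gives_bit_identical_scenes(self):
        params = SceneParams(n_components=4)
        a = generate_network(params, seed=11)
        b = generate_network(params, seed=11)
        assert a.to_json() == b.to_json()

    def test_zero_branch_probability_gives_no_branch_points(self):
        params = SceneParams(branch_prob_per_um=0.0, n_components=5)
        scene = generate_network(params, seed=2)
        assert len(scene.branch_points_um) == 0

    def test_cristae_count_matches_spacing_for_known_length(self):
        # a 3.5 um tubule at 70 nm spacing holds floor(3500/70) = 50 cristae
        scene = build_tubule_grid(1, length_um=3.5, seed=0)[0]
        comp = scene.components[0]
        assert comp.n_cristae == 50

    def test_cristae_lie_inside_tubule_envelope(self):
        scene = generate_network(SceneParams(n_components=3), seed=7)
        for comp in scene.components:
            pts = np.vstack([t.points for t in comp.tubules])
            for p0, p1 in comp.cristae:
                for end in (p0, p1):
                    d = np.min(np.linalg.norm(pts - end, axis=1))
                    assert d <= comp.radius_um + 1e-6

    def test_true_class_is_classifier_of_true_length_and_count(self):
        scene = generate_network(SceneParams(n_components=4), seed=9)
        for comp in scene.components:
            assert comp.true_class == classify_mitochondrion(
                comp.length_um, comp.n_cristae
            )

    def test_field_too_small_raises(self):
        with pytest.raises(ParameterError):
            generate_network(
                SceneParams(field_size_um=(0.5, 0.5)), seed=0
            )

    def test_invalid_spacing_thickness_raises(self):
        with pytest.raises(ParameterError):
            SceneParams(cristae_spacing_nm=10.0, cristae_thickness_nm=20.0).validate()


class TestSampleNucleoids:
    def test_full_occupancy_puts_a_nucleoid_on_every_tip(self):
        scene = build_tubule_grid(6, seed=1)[0]
        scene = sample_nucleoids(scene, NucleoidPlacement(occupancy=1.0), seed=5)
        d = nearest_distances(scene.tips_um, scene.nucleoids.centers_um)
        assert np.all(d == 0.0)

    def test_exponential_law_fraction_below_cutoff(self):
        # occupancy 0: tip nearest distances ~ Exp(rate); the closed form
        # 1 - exp(-rate * 0.6) = 0.650 should match the empirical fraction
        placement = NucleoidPlacement(occupancy=0.0, rate_per_um=TIP_RATE)
        dists = []
        for seed, scene in enumerate(build_tubule_grid(400, length_um=6.0, seed=2)):
            scene = sample_nucleoids(scene, placement, seed=100 + seed)
            dists.append(
                nearest_distances(scene.tips_um, scene.nucleoids.centers_um)
            )
        d = np.concatenate(dists)
        assert len(d) == 800
        assert fraction_below(d, 0.6) == pytest.approx(0.650, abs=0.04)

    def test_distance_law_passes_kolmogorov_smirnov(self):
        placement = NucleoidPlacement(occupancy=0.0, rate_per_um=TIP_RATE)
        dists = []
        seed = 0
        for scene in build_tubule_grid(5000, length_um=6.0, seed=3):
            scene = sample_nucleoids(scene, placement, seed=seed)
            seed += 1
            dists.append(
                nearest_distances(scene.tips_um, scene.nucleoids.centers_um)
            )
        d = np.concatenate(dists)
        assert len(d) == 10_000
        res = stats.kstest(d, "expon", args=(0, 1.0 / TIP_RATE))
        assert res.pvalue > 0.01

    def test_landmark_occupancy_observable_near_requested_rate(self):
        # fraction of tips carrying a nucleoid within one nucleoid radius;
        # slightly above the occupancy because an off-landmark exponential
        # draw can also land that close
        placement = NucleoidPlacement(occupancy=0.677)
        near = []
        for seed, scene in enumerate(build_tubule_grid(500, seed=4)):
            scene = sample_nucleoids(scene, placement, seed=200 + seed)
            d = nearest_distances(scene.tips_um, scene.nucleoids.centers_um)
            near.append(d < placement.nucleoid_diameter_nm / 2000.0)
        frac = np.concatenate(near).mean()
        assert frac == pytest.approx(0.677, abs=0.05)

    def test_occupancy_flags_are_binomial_at_requested_rate(self):
        placement = NucleoidPlacement(occupancy=0.677)
        flags = []
        for seed, scene in enumerate(build_tubule_grid(500, seed=5)):
            scene = sample_nucleoids(scene, placement, seed=300 + seed)
            flags.append(scene.landmark_occupied)
        f = np.concatenate(flags)
        se = np.sqrt(0.677 * 0.323 / len(f))
        assert abs(f.mean() - 0.677) < 4 * se

    def test_long_mean_distance_warns_and_truncates(self):
        scene = build_tubule_grid(2, length_um=2.0, seed=6)[0]
        with pytest.warns(UserWarning, match="truncated"):
            out = sample_nucleoids(
                scene, NucleoidPlacement(occupancy=0.0, rate_per_um=0.1), seed=0
            )
        # truncation keeps every nucleoid on a centerline inside the field
        w, h = scene.params.field_size_um
        assert np.all(out.nucleoids.centers_um[:, 0] <= w)

    def test_empty_scene_raises(self):
        scene = GroundTruthScene(params=SceneParams(), components=[])
        with pytest.raises(ParameterError):
            sample_nucleoids(scene, NucleoidPlacement(), seed=0)


class TestRenderDensity:
    def test_empty_scene_renders_all_zero(self):
        scene = GroundTruthScene(params=SceneParams(), components=[])
        dm = render_density(scene, "IM", 20.0)
        assert dm.values.shape == (1000, 1000)
        assert not dm.values.any()

    def test_doubling_amplitude_doubles_the_map_exactly(self):
        params = SceneParams(n_components=2)
        a = generate_network(params, seed=8)
        dm1 = render_density(a, "IM", 20.0)
        a.params.density_amplitude = 2.0
        dm2 = render_density(a, "IM", 20.0)
        np.testing.assert_allclose(dm2.values, 2.0 * dm1.values, rtol=1e-12)

    def test_nucleoid_mass_scales_with_disk_area(self):
        base = build_tubule_grid(1, seed=9)[0]
        masses = {}
        for r_nm in (120.0, 240.0):
            scene = sample_nucleoids(
                base,
                NucleoidPlacement(occupancy=1.0, nucleoid_diameter_nm=r_nm),
                seed=1,
            )
            masses[r_nm] = render_density(scene, "mtDNA", 20.0).values.sum()
        # doubling the diameter quadruples the disk area
        assert masses[240.0] / masses[120.0] == pytest.approx(4.0, rel=0.05)

    def test_im_mass_proportional_to_structure_length(self):
        short = build_tubule_grid(1, length_um=2.8, seed=10)[0]
        long = build_tubule_grid(1, length_um=5.6, seed=10)[0]
        m_short = render_density(short, "IM", 20.0).values.sum()
        m_long = render_density(long, "IM", 20.0).values.sum()
        assert m_long / m_short == pytest.approx(2.0, rel=0.05)

    def test_rendered_cristae_count_equals_truth(self):
        from skimage.measure import label as cc_label

        scene = build_tubule_grid(4, seed=11)[0]
        raster = rasterize_cristae(scene, 20.0)
        n = cc_label(raster, connectivity=2).max()
        assert n == sum(c.n_cristae for c in scene.components)

    def test_unknown_channel_rejected(self):
        scene = GroundTruthScene(params=SceneParams(), components=[])
        with pytest.raises(ParameterError):
            render_density(scene, "DAPI", 20.0)

    def test_coarse_pixels_warn_about_aliasing(self):
        scene = build_tubule_grid(1, seed=12)[0]
        with pytest.warns(UserWarning, match="aliased"):
            render_density(scene, "IM", 100.0)


class TestMorphologyPopulation:
    @pytest.mark.parametrize(
        "mixture,klass,expected",
        [((0.157, 0.169, 0.674), "III", 0.674),
         ((0.557, 0.27, 0.173), "I", 0.557)],
    )
    def test_requested_mixture_is_realized(self, mixture, klass, expected):
        df = sample_morphology_population(mixture, 10_000, seed=13)
        assert (df.true_class == klass).mean() == pytest.approx(expected, abs=0.01)

    def test_pure_class_one_respects_both_thresholds(self):
        df = sample_morphology_population((1.0, 0.0, 0.0), 500, seed=14)
        assert (df.length_um < 2.5).all()
        assert (df.n_cristae < 6).all()

    def test_labels_consistent_with_classifier(self):
        df = sample_morphology_population((0.3, 0.3, 0.4), 1000, seed=15)
        for row in df.itertuples():
            assert classify_mitochondrion(row.length_um, row.n_cristae) == row.true_class

    def test_degenerate_mixture_rejected(self):
        with pytest.raises(ParameterError):
            sample_morphology_population((0.0, 0.0, 0.0), 10, seed=0)


def test_scene_json_round_trip(network_scene):
    restored = GroundTruthScene.from_json(network_scene.to_json())
    assert restored.to_json() == network_scene.to_json()
    assert len(restored.components) == len(network_scene.components)
    np.testing.assert_allclose(
        restored.nucleoids.centers_um, network_scene.nucleoids.centers_um
    )
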