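"""The end-to-end pipeline: simulate -> acquire -> segment -> morphometry -> stats.

Real-image mode skips the first two stages and starts from TIFFs on disk.
Each run writes a manifest (config hash, package version, per-stage file
list, timestamps) sufficient to re-execute it; all CSV/TIFF outputs are
deterministic given the config and seed, so repeated runs are
byte-identical apart from manifest timestamps.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, config_hash
from .errors import EstimationError
from .imaging import Image, simulate_acquisition
from .io import read_image, write_image, write_labels, write_mask
from .morphometry import analyze_labeled_image, records_to_frame, summarize_population
from .scene import generate_network, render_density, sample_nucleoids
from .segmentation import segment_image_pair
from .spatial import build_report

__all__ = ["RunManifest", "run_pipeline"]

log = logging.getLogger("mitograph")


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages: Dict[str, List[str]] = field(default_factory=dict)
    timestamps: Dict[str, str] = field(default_factory=dict)

    def record(self, stage: str, files: List[Path]) -> None:
        self.stages[stage] = [str(f) for f in files]
        self.timestamps[stage] = _dt.datetime.now().isoformat(timespec="seconds")

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))


def run_pipeline(
    cfg: PipelineConfig,
    outdir=None,
    im_path=None,
    mtdna_path=None,
) -> RunManifest:
    """Execute the pipeline and write every stage's outputs under ``outdir``.

    With ``im_path`` (and optionally ``mtdna_path``) given, the synthetic
    and acquisition stages are skipped and segmentation starts from the
    supplied TIFFs.  Any stage error propagates after the manifest of the
    completed stages is written.
    """
    cfg.validate()
    out = Path(outdir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config_hash(cfg), version=__version__, seed=cfg.seed
    )
    manifest_path = out / "manifest.json"
    try:
        _run_stages(cfg, out, manifest, im_path, mtdna_path)
    finally:
        manifest.write(manifest_path)
    return manifest


def _run_stages(cfg, out: Path, manifest: RunManifest, im_path, mtdna_path) -> None:
    seed = cfg.seed
    if im_path is None:
        scene = generate_network(cfg.scene, seed=seed, rule=cfg.rule)
        if scene.components:
            scene = sample_nucleoids(scene, cfg.nucleoids, seed=seed + 1)
        scene_file = out / "scene.json"
        scene_file.write_text(scene.to_json())
        manifest.record("simulate", [scene_file])
        log.info(
            "simulate: %d components, %d cristae, %d nucleoids, %d tips, %d branch points",
            len(scene.components), sum(c.n_cristae for c in scene.components),
            len(scene.nucleoids), len(scene.tips_um), len(scene.branch_points_um),
        )

        px = cfg.acquisition.pixel_size_nm
        im_density = render_density(scene, "IM", px)
        mt_density = render_density(scene, "mtDNA", px)
        im_img = simulate_acquisition(im_density, cfg.acquisition, cfg.Is_mW, seed + 2)
        mt_img = simulate_acquisition(mt_density, cfg.confocal, cfg.Is_mW, seed + 3)
        im_img.channel, mt_img.channel = "IM", "mtDNA"
        im_file, mt_file = out / "im_sted.tif", out / "mtdna_confocal.tif"
        write_image(im_file, im_img)
        write_image(mt_file, mt_img)
        manifest.record("acquire", [im_file, mt_file])
        log.info("acquire: IM %s px, mtDNA %s px", im_img.counts.shape,
                 mt_img.counts.shape)
    else:
        im_img = read_image(im_path)
        mt_img = read_image(mtdna_path) if mtdna_path else None
        manifest.record("acquire", [Path(im_path)] +
                        ([Path(mtdna_path)] if mtdna_path else []))

    seg = segment_image_pair(im_img, mt_img, cfg.segmentation)
    px = im_img.pixel_size_nm
    seg_files = [out / "cristae_mask.tif", out / "mito_labels.tif",
                 out / "nucleoids.csv"]
    write_mask(seg_files[0], seg.cristae_mask, px)
    write_labels(seg_files[1], seg.labeled_mask, px)
    nuc = seg.nucleoids
    pd.DataFrame(
        {
            "id": np.arange(1, len(nuc) + 1),
            "x_um": np.round(nuc.centroids_um[:, 0], 4) if len(nuc) else [],
            "y_um": np.round(nuc.centroids_um[:, 1], 4) if len(nuc) else [],
            "area_um2": np.round(nuc.areas_um2, 6) if len(nuc) else [],
            "mito_label": nuc.owner_labels if len(nuc) else [],
        }
    ).to_csv(seg_files[2], index=False)
    manifest.record("segment", seg_files)
    n_labels = int(seg.labeled_mask.max())
    log.info("segment: %d mitochondria, %d nucleoids", n_labels, len(nuc))

    records = analyze_labeled_image(
        seg.labeled_mask, seg.cristae_mask, px, nucleoids=nuc, rule=cfg.rule,
    )
    morph_files = [out / "mitochondria.csv", out / "landmarks.csv"]
    records_to_frame(records).to_csv(morph_files[0], index=False)
    landmark_rows = []
    for r in records:
        for kind, pts in (("tip", r.tips_um), ("branch", r.branch_points_um)):
            for x, y in pts:
                landmark_rows.append(
                    {"label": r.label, "kind": kind,
                     "x_um": round(float(x), 4), "y_um": round(float(y), 4)}
                )
    pd.DataFrame(landmark_rows, columns=["label", "kind", "x_um", "y_um"]).to_csv(
        morph_files[1], index=False
    )
    manifest.record("morphometry", morph_files)
    log.info("morphometry: %d records, %d landmarks", len(records),
             len(landmark_rows))

    if not records:
        raise EstimationError("no mitochondria found: nothing to analyze")
    props, _ = summarize_population(records)
    report = build_report(records, nuc, cfg.stats, class_proportions=props)
    report_file = out / "spatial_report.json"
    report_file.write_text(report.to_json())
    dist_rows = [
        {"kind": kind, "distance_um": round(float(d), 5)}
        for kind, arr in report.distances_um.items()
        for d in arr
    ]
    dist_file = out / "distances.csv"
    pd.DataFrame(dist_rows, columns=["kind", "distance_um"]).to_csv(
        dist_file, index=False
    )
    manifest.record("stats", [report_file, dist_file])
    log.info("stats: fractions below %.2f um: %s", cfg.stats.distance_cutoff_um,
             report.fraction_below_cutoff)
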