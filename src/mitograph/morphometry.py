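"""Skeleton-based mitochondrial morphometry.

Each labeled mitochondrion (or network) is reduced to its topological
skeleton, from which geodesic length, tips (degree-1 landmarks) and branch
points (degree>=3 landmarks) are measured.  Together with the cristae count
this feeds a three-class morphology rule used to compare populations, e.g.
healthy networks versus the fragmented ellipsoids seen under
erastin-induced ferroptosis:

* Class I   - fragments: length < 2.5 um AND fewer than 6 cristae
* Class II  - intermediate: length in [2.5, 5] um OR 6-12 cristae
* Class III - networks: length > 5 um OR more than 12 cristae

The disjunctive clauses overlap; Class III is tested first, then Class II,
so that a short organelle with many cristae counts as a network.  Ties at
2.5 um / 6 cristae fall to Class II, exactly as the interval notation reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import skeletonize

from .errors import EstimationError, ParameterError

__all__ = [
    "ClassificationRule",
    "SkeletonGraph",
    "MitochondrionRecord",
    "classify_mitochondrion",
    "skeletonize_component",
    "count_cristae",
    "analyze_labeled_image",
    "summarize_population",
]


@dataclass(frozen=True)
class ClassificationRule:
    """Length/cristae-count thresholds of the three-class morphology rule."""

    length_low_um: float = 2.5
    length_high_um: float = 5.0
    cristae_low: int = 6
    cristae_high: int = 12

    def __post_init__(self) -> None:
        if not (0 < self.length_low_um < self.length_high_um):
            raise ParameterError("need 0 < length_low < length_high")
        if not (0 < self.cristae_low < self.cristae_high):
            raise ParameterError("need 0 < cristae_low < cristae_high")


def classify_mitochondrion(
    length_um: float, n_cristae: int, rule: ClassificationRule = ClassificationRule()
) -> str:
    """Assign a mitochondrion to morphology class ``"I"``, ``"II"`` or ``"III"``.

    The rule is a total function on [0, inf) x {0, 1, ...}: Class III when
    length > length_high OR count > cristae_high; otherwise Class II when
    length >= length_low OR count >= cristae_low; otherwise Class I.
    """
    if length_um < 0 or n_cristae < 0:
        raise ParameterError("length and cristae count must be non-negative")
    if length_um > rule.length_high_um or n_cristae > rule.cristae_high:
        return "III"
    if length_um >= rule.length_low_um or n_cristae >= rule.cristae_low:
        return "II"
    return "I"


# ---------------------------------------------------------------------------
# Skeletons
# ---------------------------------------------------------------------------

_ORTH = ((-1, 0), (1, 0), (0, -1), (0, 1))
_DIAG = ((-1, -1), (-1, 1), (1, -1), (1, 1))


@dataclass
class SkeletonGraph:
    """Skeleton of one labeled component as a pixel graph.

    ``graph`` has one node per skeleton pixel (row, col) with edges between
    8-adjacent pixels; diagonal edges that merely close a right-angle
    triangle are dropped so a staircase is not double counted.  Lengths are
    in um (orthogonal step = 1 px, diagonal = sqrt(2) px).
    """

    label: int
    pixel_size_nm: float
    graph: nx.Graph
    tips_um: np.ndarray          # (n_tips, 2) as (x, y) in um
    branch_points_um: np.ndarray  # (n_branch, 2) as (x, y) in um
    total_length_um: float

    @property
    def n_tips(self) -> int:
        return len(self.tips_um)

    @property
    def n_branch_points(self) -> int:
        return len(self.branch_points_um)


def _pixel_graph(skel: np.ndarray, px_um: float) -> nx.Graph:
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    coords = set(zip(rows.tolist(), cols.tolist()))
    g.add_nodes_from(coords)
    for r, c in coords:
        for dr, dc in _ORTH:
            q = (r + dr, c + dc)
            if q in coords:
                g.add_edge((r, c), q, length=px_um)
    for r, c in coords:
        for dr, dc in _DIAG:
            q = (r + dr, c + dc)
            if q not in coords or g.has_edge((r, c), q):
                continue
            # skip the diagonal if an orthogonal 2-step path exists
            if ((r, c + dc) in coords) or ((r + dr, c) in coords):
                continue
            g.add_edge((r, c), q, length=px_um * np.sqrt(2.0))
    return g


def _prune_spurs(g: nx.Graph, min_len_um: float) -> nx.Graph:
    """Remove terminal twigs shorter than ``min_len_um`` that end at a junction.

    Skeletonization of a pixelated tube leaves short lateral spurs near
    boundary bumps; real side branches are much longer than the tube radius.
    """
    g = g.copy()
    changed = True
    while changed:
        changed = False
        tips = [n for n in g.nodes if g.degree(n) == 1]
        for tip in tips:
            if tip not in g:
                continue
            path = [tip]
            length = 0.0
            cur, prev = tip, None
            while True:
                nbrs = [n for n in g.neighbors(cur) if n != prev]
                if g.degree(cur) >= 3 or not nbrs:
                    break
                nxt = nbrs[0]
                length += g.edges[cur, nxt]["length"]
                prev, cur = cur, nxt
                path.append(cur)
                if g.degree(cur) >= 3 or length > min_len_um:
                    break
            # prune only if the walk hit a junction quickly
            if length <= min_len_um and g.degree(cur) >= 3:
                g.remove_nodes_from(path[:-1])
                changed = True
    return g


def _extend_tip(
    g: nx.Graph, tip: Tuple[int, int], mask: np.ndarray, max_steps: int = 40
) -> Tuple[Tuple[float, float], float]:
    """Walk a tip outward along its local direction to the mask boundary.

    Returns the extended tip position (row, col, possibly fractional) and
    the number of pixels added.
    """
    # local direction from a few pixels back along the skeleton
    path = [tip]
    cur, prev = tip, None
    for _ in range(5):
        nbrs = [n for n in g.neighbors(cur) if n != prev]
        if not nbrs:
            break
        prev, cur = cur, nbrs[0]
        path.append(cur)
    if len(path) < 2:
        return (float(tip[0]), float(tip[1])), 0.0
    d = np.asarray(tip, dtype=float) - np.asarray(path[-1], dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        return (float(tip[0]), float(tip[1])), 0.0
    d /= norm
    pos = np.asarray(tip, dtype=float)
    steps = 0
    ny, nx_ = mask.shape
    while steps < max_steps:
        nxt = pos + d
        r, c = int(round(nxt[0])), int(round(nxt[1]))
        if not (0 <= r < ny and 0 <= c < nx_) or not mask[r, c]:
            break
        pos = nxt
        steps += 1
    return (float(pos[0]), float(pos[1])), float(steps)


def _merge_landmarks(points_px: List[Tuple[int, int]], radius_px: float) -> np.ndarray:
    """Merge nearby landmark pixels into single landmarks (cluster centroids)."""
    if not points_px:
        return np.empty((0, 2))
    pts = np.asarray(points_px, dtype=float)
    merged: List[np.ndarray] = []
    used = np.zeros(len(pts), dtype=bool)
    for i in range(len(pts)):
        if used[i]:
            continue
        close = np.linalg.norm(pts - pts[i], axis=1) <= radius_px
        grp = pts[close & ~used]
        used |= close
        merged.append(grp.mean(axis=0))
    return np.asarray(merged)


def skeletonize_component(
    labeled_mask: np.ndarray,
    label: int,
    pixel_size_nm: float,
    prune_spur_um: float = 0.2,
    merge_radius_px: float = 3.0,
    smooth_radius_nm: float = 60.0,
) -> SkeletonGraph:
    """Skeletonize one labeled component and extract tips and branch points.

    The mask boundary of a reconstructed tubule is scalloped by the crista
    ends, which makes a raw skeleton meander and over-count length; a
    median smoothing at ``smooth_radius_nm`` removes the scallops first
    (skipped automatically when it would erase a thin structure).
    Branch-point pixels (>=3 skeleton neighbours) within ``merge_radius_px``
    of each other are merged into a single landmark; tips are degree-1
    pixels after spur pruning.
    """
    mask = labeled_mask == label
    if not mask.any():
        raise LookupError(f"label {label} not present in mask")
    px_um = pixel_size_nm / 1000.0
    if smooth_radius_nm > 0:
        from skimage.morphology import disk

        r = max(int(round(smooth_radius_nm / pixel_size_nm)), 1)
        smoothed = ndi.median_filter(mask, footprint=disk(r))
        if smoothed.sum() >= 0.8 * mask.sum():
            mask = smoothed
    skel = skeletonize(mask)
    g = _pixel_graph(skel, px_um)
    g = _prune_spurs(g, prune_spur_um)
    total = sum(d["length"] for _, _, d in g.edges(data=True))

    tip_px = [n for n in g.nodes if g.degree(n) == 1]
    branch_px = [n for n in g.nodes if g.degree(n) >= 3]
    branch = _merge_landmarks(branch_px, merge_radius_px)
    # thinning retracts the skeleton from a rounded end by about the tube
    # half-width: push each tip back out to the mask boundary
    raw_mask = labeled_mask == label
    extended = []
    for tip in tip_px:
        new_tip, extra = _extend_tip(g, tip, raw_mask)
        extended.append(new_tip)
        total += extra * px_um
    tip_px = extended
    # (row, col) -> (x, y) um
    to_um = lambda a: (
        np.column_stack([a[:, 1], a[:, 0]]) * px_um if len(a) else np.empty((0, 2))
    )
    tips = to_um(np.asarray(tip_px, dtype=float).reshape(-1, 2))
    return SkeletonGraph(
        label=label,
        pixel_size_nm=pixel_size_nm,
        graph=g,
        tips_um=tips,
        branch_points_um=to_um(branch),
        total_length_um=float(total),
    )


def count_cristae(
    label: int, cristae_mask: np.ndarray, labeled_mask: np.ndarray
) -> int:
    """Count cristae belonging to one mitochondrion.

    A crista is a connected component (8-connectivity) of the cristae mask;
    it belongs to the mitochondrion whose label lies under its centroid
    (majority vote over its pixels when the centroid falls on background).
    """
    comps = cc_label(cristae_mask > 0, connectivity=2)
    n = 0
    for prop in regionprops(comps):
        r, c = (int(round(v)) for v in prop.centroid)
        r = min(max(r, 0), labeled_mask.shape[0] - 1)
        c = min(max(c, 0), labeled_mask.shape[1] - 1)
        owner = labeled_mask[r, c]
        if owner == 0:
            rows, cols = prop.coords[:, 0], prop.coords[:, 1]
            vals = labeled_mask[rows, cols]
            vals = vals[vals > 0]
            owner = np.bincount(vals).argmax() if len(vals) else 0
        if owner == label:
            n += 1
    return n


# ---------------------------------------------------------------------------
# Per-mitochondrion records
# ---------------------------------------------------------------------------


@dataclass
class MitochondrionRecord:
    label: int
    length_um: float
    n_cristae: int
    morph_class: str
    mito_area_um2: float
    cristae_area_um2: float
    nucleoid_area_um2: float = 0.0
    tips_um: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    branch_points_um: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))


def analyze_labeled_image(
    labeled_mask: np.ndarray,
    cristae_mask: np.ndarray,
    pixel_size_nm: float,
    nucleoids=None,
    rule: ClassificationRule = ClassificationRule(),
    end_halo_um: float = 0.09,
) -> List[MitochondrionRecord]:
    """Measure every labeled mitochondrion in an image.

    Skeleton tips are extended to the mask boundary, which lies about half
    the effective PSF FWHM beyond the true structure end (the threshold
    halo); ``end_halo_um`` is subtracted once per tip to compensate.  Set
    it to 0 to report raw extended-skeleton length.  ``nucleoids`` is an
    optional NucleoidSet whose per-nucleoid areas are attributed to their
    owning label.
    """
    px_area = (pixel_size_nm / 1000.0) ** 2
    labels = np.unique(labeled_mask)
    labels = labels[labels > 0]
    nuc_area: Dict[int, float] = {}
    if nucleoids is not None:
        for owner, area in zip(nucleoids.owner_labels, nucleoids.areas_um2):
            nuc_area[int(owner)] = nuc_area.get(int(owner), 0.0) + float(area)

    comps = cc_label(cristae_mask > 0, connectivity=2)
    # precompute crista ownership once (same rule as count_cristae)
    counts: Dict[int, int] = {}
    areas_cristae: Dict[int, float] = {}
    for prop in regionprops(comps):
        r, c = (int(round(v)) for v in prop.centroid)
        r = min(max(r, 0), labeled_mask.shape[0] - 1)
        c = min(max(c, 0), labeled_mask.shape[1] - 1)
        owner = int(labeled_mask[r, c])
        if owner == 0:
            vals = labeled_mask[prop.coords[:, 0], prop.coords[:, 1]]
            vals = vals[vals > 0]
            owner = int(np.bincount(vals).argmax()) if len(vals) else 0
        if owner:
            counts[owner] = counts.get(owner, 0) + 1
            areas_cristae[owner] = areas_cristae.get(owner, 0.0) + prop.area * px_area

    records = []
    for lab in labels:
        lab = int(lab)
        sg = skeletonize_component(labeled_mask, lab, pixel_size_nm)
        length = max(sg.total_length_um - end_halo_um * sg.n_tips,
                     pixel_size_nm / 1000.0)
        n_cr = counts.get(lab, 0)
        records.append(
            MitochondrionRecord(
                label=lab,
                length_um=length,
                n_cristae=n_cr,
                morph_class=classify_mitochondrion(length, n_cr, rule),
                mito_area_um2=float((labeled_mask == lab).sum() * px_area),
                cristae_area_um2=areas_cristae.get(lab, 0.0),
                nucleoid_area_um2=nuc_area.get(lab, 0.0),
                tips_um=sg.tips_um,
                branch_points_um=sg.branch_points_um,
            )
        )
    return records


def summarize_population(records: Sequence[MitochondrionRecord]):
    """Class proportions and the per-record (length, count, class) table.

    Returns ``(proportions, table)`` where ``proportions`` maps class name
    to fraction (summing to 1) and ``table`` is a DataFrame with one row per
    mitochondrion.
    """
    if len(records) == 0:
        raise EstimationError("no mitochondria to summarize")
    table = pd.DataFrame(
        {
            "label": [r.label for r in records],
            "length_um": [r.length_um for r in records],
            "n_cristae": [r.n_cristae for r in records],
            "class": [r.morph_class for r in records],
        }
    )
    props = {
        k: float((table["class"] == k).mean()) for k in ("I", "II", "III")
    }
    return props, table


def records_to_frame(records: Sequence[MitochondrionRecord]) -> pd.DataFrame:
    """Flatten records to the CSV schema used by the pipeline."""
    return pd.DataFrame(
        {
            "label": [r.label for r in records],
            "length_um": [round(r.length_um, 6) for r in records],
            "n_cristae": [r.n_cristae for r in records],
            "class": [r.morph_class for r in records],
            "mito_area_um2": [round(r.mito_area_um2, 6) for r in records],
            "cristae_area_um2": [round(r.cristae_area_um2, 6) for r in records],
            "nucleoid_area_um2": [round(r.nucleoid_area_um2, 6) for r in records],
        }
    )
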