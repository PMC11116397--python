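"""Synthetic ground-truth scenes of mitochondrial networks.

Vector scenes emulate the specimens seen in live-cell STED imaging of the
inner membrane: tubules 200-700 nm in diameter whose cristae are transverse
segments spaced ~70 nm apart, with mtDNA nucleoids preferentially sitting
at tips and branch points of the network.  Scenes carry full ground truth
(centerlines, landmarks, per-component length / cristae count / morphology
class) so that every downstream stage - image formation, segmentation,
morphometry, spatial statistics - can be validated without microscope data.

Conventions (used everywhere in the package): coordinates are continuous,
in um, origin at the field corner, x along columns and y along rows; the
center of pixel ``(i, j)`` (0-based row, col) is at ``(x, y) = (j, i) * p``
for pixel size ``p``.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ParameterError
from .morphometry import ClassificationRule, classify_mitochondrion

__all__ = [
    "SceneParams",
    "NucleoidPlacement",
    "Tubule",
    "TubuleComponent",
    "NucleoidTruth",
    "GroundTruthScene",
    "DensityMap",
    "generate_network",
    "sample_nucleoids",
    "render_density",
    "rasterize_cristae",
    "rasterize_tubules",
    "sample_morphology_population",
    "build_population_scenes",
    "build_tubule_grid",
    "control_nucleoid_placement",
]

# Linear nucleoid density (per um of tubule) emulating the control
# condition; calibrated once so that the full pipeline's measured
# mtDNA/mitochondrion area ratio reproduces the control value (see
# docs/methods.md, "Control calibration").
CONTROL_NUCLEOIDS_PER_UM = 0.55


@dataclass
class SceneParams:
    """Geometry of a synthetic field of mitochondrial tubules.

    Lengths are in the units named by each field.  ``density_amplitude`` is
    the fluorophore density deposited per um of painted line (arbitrary
    units); the inner boundary membrane is painted at
    ``membrane_amplitude_ratio`` times the cristae amplitude.
    """

    field_size_um: Tuple[float, float] = (20.0, 20.0)
    tubule_diameter_range_nm: Tuple[float, float] = (200.0, 700.0)
    cristae_spacing_nm: float = 70.0
    cristae_thickness_nm: float = 20.0
    n_components: int = 5
    branch_prob_per_um: float = 0.15
    density_amplitude: float = 1.0
    tubule_length_range_um: Tuple[float, float] = (3.0, 8.0)
    membrane_amplitude_ratio: float = 0.3
    cristae_halfwidth_ratio: float = 0.75   # crista half-length / tubule radius
    step_um: float = 0.05
    heading_sigma: float = 0.10             # rad per growth step (curvature cap)

    def validate(self) -> None:
        w, h = self.field_size_um
        dmin, dmax = self.tubule_diameter_range_nm
        if not (0 < dmin <= dmax):
            raise ParameterError("tubule diameter range must be positive and ordered")
        if dmax / 1000.0 >= min(w, h):
            raise ParameterError("diameter range must lie within the field size")
        if min(w, h) < dmin / 1000.0 + 1.0:
            raise ParameterError("field too small to host one tubule of minimum diameter")
        if not (self.cristae_spacing_nm > self.cristae_thickness_nm > 0):
            raise ParameterError("need cristae spacing > cristae thickness > 0")
        if self.n_components < 0 or self.branch_prob_per_um < 0:
            raise ParameterError("counts and probabilities must be non-negative")
        if not (0 < self.cristae_halfwidth_ratio < 1):
            raise ParameterError("cristae must lie within the tubule envelope")


@dataclass
class NucleoidPlacement:
    """How mtDNA nucleoids are distributed relative to the network.

    Each tip / branch point is independently occupied by a nucleoid with
    ``occupancy``; an unoccupied landmark instead gets a nucleoid placed
    along the tubule at an Exponential(``rate_per_um``) arc distance, so
    landmark nearest-nucleoid distances follow the exponential law seen in
    the tip/branch-point distance histograms.  Additional "interior"
    nucleoids are a Poisson process along the tubules at
    ``interior_per_um``.
    """

    occupancy: float = 0.677
    rate_per_um: float = 1.7470   # -ln(0.35)/0.6: 65% of distances < 0.6 um
    nucleoid_diameter_nm: float = 120.0
    interior_per_um: float = 0.0

    def validate(self) -> None:
        if not (0.0 <= self.occupancy <= 1.0):
            raise ParameterError("occupancy must be in [0, 1]")
        if self.rate_per_um <= 0:
            raise ParameterError("exponential rate must be positive")
        if self.nucleoid_diameter_nm <= 0 or self.interior_per_um < 0:
            raise ParameterError("invalid nucleoid parameters")


def control_nucleoid_placement() -> NucleoidPlacement:
    """Defaults emulating the untreated (control) condition."""
    return NucleoidPlacement(interior_per_um=CONTROL_NUCLEOIDS_PER_UM)


@dataclass
class Tubule:
    """One polyline of a component: points (n, 2) in um, resampled at ~step."""

    points: np.ndarray

    @property
    def seg_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def length_um(self) -> float:
        return float(self.seg_lengths.sum())

    def point_at(self, s: float) -> np.ndarray:
        """Point at arc length ``s`` from the first vertex (clamped)."""
        cum = np.concatenate([[0.0], np.cumsum(self.seg_lengths)])
        s = float(np.clip(s, 0.0, cum[-1]))
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(cum) - 2)
        seg = cum[i + 1] - cum[i]
        t = 0.0 if seg == 0 else (s - cum[i]) / seg
        return self.points[i] * (1 - t) + self.points[i + 1] * t

    def tangent_at(self, s: float) -> np.ndarray:
        cum = np.concatenate([[0.0], np.cumsum(self.seg_lengths)])
        s = float(np.clip(s, 0.0, cum[-1]))
        i = min(int(np.searchsorted(cum, s, side="right") - 1), len(cum) - 2)
        d = self.points[i + 1] - self.points[i]
        n = np.linalg.norm(d)
        return d / n if n else np.array([1.0, 0.0])


@dataclass
class TubuleComponent:
    """One mitochondrion / network: polylines sharing a radius, plus truth."""

    radius_um: float
    tubules: List[Tubule]
    branch_points_um: np.ndarray          # (n, 2)
    tips_um: np.ndarray                   # (n, 2)
    cristae: List[Tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    length_um: float = 0.0
    n_cristae: int = 0
    true_class: str = ""


@dataclass
class NucleoidTruth:
    centers_um: np.ndarray                # (n, 2)
    radii_um: np.ndarray                  # (n,)
    kinds: np.ndarray                     # "landmark" | "interior"

    def __len__(self) -> int:
        return len(self.centers_um)

    @staticmethod
    def empty() -> "NucleoidTruth":
        return NucleoidTruth(
            np.empty((0, 2)), np.empty(0), np.empty(0, dtype=object)
        )


@dataclass
class GroundTruthScene:
    params: SceneParams
    components: List[TubuleComponent]
    nucleoids: NucleoidTruth = field(default_factory=NucleoidTruth.empty)
    landmark_occupied: Optional[np.ndarray] = None  # per landmark, after sampling

    @property
    def tips_um(self) -> np.ndarray:
        arrs = [c.tips_um for c in self.components if len(c.tips_um)]
        return np.vstack(arrs) if arrs else np.empty((0, 2))

    @property
    def branch_points_um(self) -> np.ndarray:
        arrs = [c.branch_points_um for c in self.components if len(c.branch_points_um)]
        return np.vstack(arrs) if arrs else np.empty((0, 2))

    @property
    def total_length_um(self) -> float:
        return sum(c.length_um for c in self.components)

    # -- JSON round trip (vector truth only) --------------------------------
    def to_json(self) -> str:
        def arr(a):
            return np.asarray(a).tolist()

        return json.dumps(
            {
                "params": asdict(self.params),
                "components": [
                    {
                        "radius_um": c.radius_um,
                        "tubules": [arr(t.points) for t in c.tubules],
                        "branch_points_um": arr(c.branch_points_um),
                        "tips_um": arr(c.tips_um),
                        "cristae": [[arr(p0), arr(p1)] for p0, p1 in c.cristae],
                        "length_um": c.length_um,
                        "n_cristae": c.n_cristae,
                        "true_class": c.true_class,
                    }
                    for c in self.components
                ],
                "nucleoids": {
                    "centers_um": arr(self.nucleoids.centers_um),
                    "radii_um": arr(self.nucleoids.radii_um),
                    "kinds": arr(self.nucleoids.kinds),
                },
            }
        )

    @staticmethod
    def from_json(text: str) -> "GroundTruthScene":
        d = json.loads(text)
        params = SceneParams(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in d["params"].items()
        })
        comps = []
        for c in d["components"]:
            comps.append(
                TubuleComponent(
                    radius_um=c["radius_um"],
                    tubules=[Tubule(np.asarray(p)) for p in c["tubules"]],
                    branch_points_um=np.asarray(c["branch_points_um"]).reshape(-1, 2),
                    tips_um=np.asarray(c["tips_um"]).reshape(-1, 2),
                    cristae=[(np.asarray(p0), np.asarray(p1)) for p0, p1 in c["cristae"]],
                    length_um=c["length_um"],
                    n_cristae=c["n_cristae"],
                    true_class=c["true_class"],
                )
            )
        nuc = d["nucleoids"]
        nucleoids = NucleoidTruth(
            np.asarray(nuc["centers_um"]).reshape(-1, 2),
            np.asarray(nuc["radii_um"], dtype=float),
            np.asarray(nuc["kinds"], dtype=object),
        )
        return GroundTruthScene(params=params, components=comps, nucleoids=nucleoids)


@dataclass
class DensityMap:
    """Continuous fluorophore density on a pixel grid (values >= 0)."""

    values: np.ndarray
    pixel_size_nm: float
    channel: str  # "IM" | "mtDNA"


# ---------------------------------------------------------------------------
# Network growth
# ---------------------------------------------------------------------------


def _grow_polyline(
    rng: np.random.Generator,
    start: np.ndarray,
    heading: float,
    target_len: float,
    params: SceneParams,
    obstacles: List[Tuple[np.ndarray, float]],
    self_radius: float,
) -> np.ndarray:
    """Random-walk a centerline with a curvature cap, steering off walls and
    stopping early on collision with other components."""
    w, h = params.field_size_um
    margin = self_radius + 0.3
    step = params.step_um
    pts = [start.copy()]
    pos = start.copy()
    length = 0.0
    while length < target_len:
        heading += rng.normal(0.0, params.heading_sigma)
        d = np.array([np.cos(heading), np.sin(heading)])
        # steer away from the field boundary
        center_pull = np.array([w / 2, h / 2]) - pos
        if (
            pos[0] < margin or pos[0] > w - margin
            or pos[1] < margin or pos[1] > h - margin
        ):
            heading = np.arctan2(center_pull[1], center_pull[0]) + rng.normal(0, 0.2)
            d = np.array([np.cos(heading), np.sin(heading)])
        nxt = pos + d * step
        hit = False
        for opts, orad in obstacles:
            if len(opts) and np.min(np.linalg.norm(opts - nxt, axis=1)) < (
                self_radius + orad + 0.5
            ):
                hit = True
                break
        if hit:
            break
        pts.append(nxt)
        pos = nxt
        length += step
    return np.asarray(pts)


def _place_cristae_on_tubule(
    tub: Tubule,
    spacing_um: float,
    half_len_um: float,
    exclusion_centers: np.ndarray,
    exclusion_radius_um: float,
    target_positions: Optional[np.ndarray] = None,
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Transverse segments at ``(k + 1/2) * spacing`` along the arc.

    Positions within ``exclusion_radius_um`` of a junction are skipped,
    mirroring the void left where branches meet.  ``target_positions``
    overrides the regular grid (used to hit a prescribed cristae count).
    """
    L = tub.length_um
    if target_positions is None:
        n = int(np.ceil(L / spacing_um - 0.5))
        positions = (np.arange(max(n, 0)) + 0.5) * spacing_um
        positions = positions[positions < L]
    else:
        positions = target_positions
    out = []
    for s in positions:
        p = tub.point_at(s)
        if len(exclusion_centers) and np.min(
            np.linalg.norm(exclusion_centers - p, axis=1)
        ) < exclusion_radius_um:
            continue
        t = tub.tangent_at(s)
        nrm = np.array([-t[1], t[0]])
        out.append((p - nrm * half_len_um, p + nrm * half_len_um))
    return out


def generate_network(
    params: SceneParams, seed: int, rule: ClassificationRule = ClassificationRule()
) -> GroundTruthScene:
    """Grow a field of tubular components with transverse cristae.

    Deterministic given ``seed``.  Branch polylines are grafted at random
    arc-length positions of their parent with probability
    ``branch_prob_per_um`` per um of growth; cristae sit perpendicular to
    the local centerline at the configured spacing, skipping a one-radius
    clearance around each junction.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    w, h = params.field_size_um
    dmin, dmax = params.tubule_diameter_range_nm
    spacing = params.cristae_spacing_nm / 1000.0
    obstacles: List[Tuple[np.ndarray, float]] = []
    components: List[TubuleComponent] = []

    for _ in range(params.n_components):
        radius = rng.uniform(dmin, dmax) / 2000.0  # nm diameter -> um radius
        target = rng.uniform(*params.tubule_length_range_um)
        start = np.array(
            [rng.uniform(radius + 0.5, w - radius - 0.5),
             rng.uniform(radius + 0.5, h - radius - 0.5)]
        )
        heading = rng.uniform(0, 2 * np.pi)
        main = _grow_polyline(rng, start, heading, target, params, obstacles, radius)
        if len(main) < 4:
            continue
        tubules = [Tubule(main)]
        branch_pts: List[np.ndarray] = []
        # expected branches ~ branch_prob_per_um * length
        main_t = tubules[0]
        n_branch = rng.poisson(params.branch_prob_per_um * main_t.length_um)
        for _ in range(min(n_branch, 3)):
            s0 = rng.uniform(0.15, 0.85) * main_t.length_um
            p0 = main_t.point_at(s0)
            t0 = main_t.tangent_at(s0)
            base = np.arctan2(t0[1], t0[0])
            ang = base + rng.choice([-1, 1]) * rng.uniform(np.pi / 4, np.pi * 5 / 12)
            blen = rng.uniform(0.25, 0.6) * target
            # branches may not collide with other components (own tubule ok)
            child = _grow_polyline(rng, p0, ang, blen, params, obstacles, radius)
            if len(child) >= 4 and Tubule(child).length_um > 4 * spacing:
                tubules.append(Tubule(child))
                branch_pts.append(p0)

        branch_arr = (
            np.vstack(branch_pts) if branch_pts else np.empty((0, 2))
        )
        tips = [tubules[0].points[0], tubules[0].points[-1]]
        tips += [t.points[-1] for t in tubules[1:]]  # child start is a junction
        tips_arr = np.vstack(tips)

        cristae: List[Tuple[np.ndarray, np.ndarray]] = []
        # the void left at a junction is nucleoid-sized, not radius-sized
        junction_clear = min(radius, 0.15)
        for t in tubules:
            cristae.extend(
                _place_cristae_on_tubule(
                    t, spacing, params.cristae_halfwidth_ratio * radius,
                    branch_arr, junction_clear,
                )
            )
        length = sum(t.length_um for t in tubules)
        comp = TubuleComponent(
            radius_um=radius,
            tubules=tubules,
            branch_points_um=branch_arr,
            tips_um=tips_arr,
            cristae=cristae,
            length_um=length,
            n_cristae=len(cristae),
            true_class=classify_mitochondrion(length, len(cristae), rule),
        )
        components.append(comp)
        for t in tubules:
            obstacles.append((t.points, radius))

    return GroundTruthScene(params=params, components=components)


# ---------------------------------------------------------------------------
# Nucleoid sampling
# ---------------------------------------------------------------------------


def _landmark_walks(comp: TubuleComponent) -> List[Tuple[np.ndarray, Tubule, float, int]]:
    """For each landmark: (position, tubule to walk along, start arc s, direction)."""
    walks = []
    for i, t in enumerate(comp.tubules):
        if i == 0:
            walks.append((t.points[0], t, 0.0, +1))       # tip at start
            walks.append((t.points[-1], t, t.length_um, -1))  # tip at end
        else:
            walks.append((t.points[-1], t, t.length_um, -1))  # branch free end
    for bp in comp.branch_points_um:
        # walk along the main tubule from the junction, random direction set
        # by the caller via rng; stored with direction 0 as a sentinel
        walks.append((bp, comp.tubules[0], None, 0))
    return walks


def sample_nucleoids(
    scene: GroundTruthScene,
    placement: NucleoidPlacement,
    seed: int,
) -> GroundTruthScene:
    """Attach nucleoids to a scene (returns an augmented copy).

    Each landmark (tip or branch point) is independently occupied with
    probability ``placement.occupancy``; otherwise its dedicated nucleoid is
    placed along the tubule at an Exp(rate) arc distance (truncated at the
    tubule end, with a warning when the exponential mean exceeds every
    tubule).  Interior nucleoids follow a Poisson line process.  All centers
    lie on centerlines, hence inside the tubule envelopes.
    """
    placement.validate()
    if not scene.components:
        raise ParameterError("scene has no tubules")
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(scene)
    r_nuc = placement.nucleoid_diameter_nm / 2000.0

    mean_d = 1.0 / placement.rate_per_um
    max_len = max(
        (t.length_um for c in scene.components for t in c.tubules), default=0.0
    )
    if mean_d > max_len:
        warnings.warn(
            "exponential mean distance exceeds the longest tubule; "
            "distances will be truncated",
            stacklevel=2,
        )

    centers: List[np.ndarray] = []
    kinds: List[str] = []
    occupied_flags: List[bool] = []
    for comp in out.components:
        for pos, tub, s0, direction in _landmark_walks(comp):
            occ = rng.random() < placement.occupancy
            occupied_flags.append(occ)
            if occ:
                centers.append(np.asarray(pos, dtype=float))
                kinds.append("landmark")
                continue
            d = rng.exponential(mean_d)
            if direction == 0:  # branch point: walk the main tubule either way
                cum = np.concatenate(
                    [[0.0], np.cumsum(tub.seg_lengths)]
                )
                s_here = cum[np.argmin(np.linalg.norm(tub.points - pos, axis=1))]
                direction = rng.choice([-1, 1])
                s = s_here + direction * d
            else:
                s = s0 + direction * d
            centers.append(tub.point_at(s))
            kinds.append("landmark")
        # interior Poisson process along all tubules of the component
        for tub in comp.tubules:
            k = rng.poisson(placement.interior_per_um * tub.length_um)
            for s in rng.uniform(0, tub.length_um, size=k):
                centers.append(tub.point_at(s))
                kinds.append("interior")

    n = len(centers)
    out.nucleoids = NucleoidTruth(
        centers_um=np.vstack(centers) if n else np.empty((0, 2)),
        radii_um=np.full(n, r_nuc),
        kinds=np.asarray(kinds, dtype=object),
    )
    out.landmark_occupied = np.asarray(occupied_flags, dtype=bool)
    return out


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def _grid_shape(params: SceneParams, px_um: float) -> Tuple[int, int]:
    w, h = params.field_size_um
    return int(round(h / px_um)), int(round(w / px_um))


def _splat_segments(
    grid: np.ndarray,
    segments: Sequence[Tuple[np.ndarray, np.ndarray]],
    px_um: float,
    amplitude: float,
) -> None:
    """Deposit line integrals of ``amplitude`` per um with bilinear weights."""
    ny, nx = grid.shape
    for p0, p1 in segments:
        L = float(np.linalg.norm(p1 - p0))
        if L == 0:
            continue
        n = max(int(np.ceil(L / (px_um / 3.0))), 2)
        ts = (np.arange(n) + 0.5) / n
        pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
        wseg = amplitude * L / n
        cx = pts[:, 0] / px_um   # pixel centers at index*px
        cy = pts[:, 1] / px_um
        j0 = np.floor(cx).astype(int)
        i0 = np.floor(cy).astype(int)
        fx = cx - j0
        fy = cy - i0
        for di, dj, wgt in (
            (0, 0, (1 - fx) * (1 - fy)),
            (0, 1, fx * (1 - fy)),
            (1, 0, (1 - fx) * fy),
            (1, 1, fx * fy),
        ):
            ii = i0 + di
            jj = j0 + dj
            ok = (ii >= 0) & (ii < ny) & (jj >= 0) & (jj < nx)
            np.add.at(grid, (ii[ok], jj[ok]), wseg * wgt[ok])


def _polyline_segments(points: np.ndarray) -> List[Tuple[np.ndarray, np.ndarray]]:
    return [(points[i], points[i + 1]) for i in range(len(points) - 1)]


def _offset_polylines(points: np.ndarray, r: float) -> List[np.ndarray]:
    d = np.gradient(points, axis=0)
    nrm = np.linalg.norm(d, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    t = d / nrm
    n = np.column_stack([-t[:, 1], t[:, 0]])
    return [points + r * n, points - r * n]


def render_density(
    scene: GroundTruthScene, channel: str, pixel_size_nm: float
) -> DensityMap:
    """Rasterize the scene into a continuous fluorophore-density map.

    ``IM`` paints the cristae plus the inner boundary membrane (offset
    curves at +/- the tubule radius, at a reduced amplitude); ``mtDNA``
    paints the nucleoid disks.  Cristae/membrane lines have a Gaussian
    cross profile of FWHM ``cristae_thickness_nm``.
    """
    if channel not in ("IM", "mtDNA"):
        raise ParameterError(f"unknown channel {channel!r}")
    params = scene.params
    if pixel_size_nm > params.cristae_spacing_nm:
        warnings.warn("pixel size exceeds cristae spacing: ground truth is aliased",
                      stacklevel=2)
    px_um = pixel_size_nm / 1000.0
    ny, nx = _grid_shape(params, px_um)
    grid = np.zeros((ny, nx))
    amp = params.density_amplitude

    if channel == "IM":
        for comp in scene.components:
            _splat_segments(grid, comp.cristae, px_um, amp)
            for tub in comp.tubules:
                for off in _offset_polylines(tub.points, comp.radius_um):
                    _splat_segments(
                        grid, _polyline_segments(off), px_um,
                        amp * params.membrane_amplitude_ratio,
                    )
        sigma_px = (params.cristae_thickness_nm / 2.3548) / pixel_size_nm
        if sigma_px > 0.05:
            from scipy.ndimage import gaussian_filter

            grid = gaussian_filter(grid, sigma_px, mode="constant")
    else:
        nuc = scene.nucleoids
        for (x, y), r in zip(nuc.centers_um, nuc.radii_um):
            r_px = r / px_um
            cx, cy = x / px_um, y / px_um
            j0 = max(int(np.floor(cx - r_px - 2)), 0)
            j1 = min(int(np.ceil(cx + r_px + 2)) + 1, nx)
            i0 = max(int(np.floor(cy - r_px - 2)), 0)
            i1 = min(int(np.ceil(cy + r_px + 2)) + 1, ny)
            if j0 >= j1 or i0 >= i1:
                continue
            jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
            dist = np.hypot(jj - cx, ii - cy)
            cov = np.clip(r_px - dist + 0.5, 0.0, 1.0)
            grid[i0:i1, j0:j1] += amp * cov

    np.maximum(grid, 0.0, out=grid)
    return DensityMap(values=grid, pixel_size_nm=pixel_size_nm, channel=channel)


def _rasterize_distance(
    shape: Tuple[int, int],
    segments: Sequence[Tuple[np.ndarray, np.ndarray]],
    px_um: float,
    half_width_um,
) -> np.ndarray:
    """Binary raster of pixels whose center is within half_width of a segment.

    ``half_width_um`` may be a scalar or a per-segment sequence.
    """
    ny, nx = shape
    out = np.zeros(shape, dtype=bool)
    hw = np.broadcast_to(np.asarray(half_width_um, dtype=float), (len(segments),))
    for (p0, p1), h in zip(segments, hw):
        lo = np.minimum(p0, p1) - h - px_um
        hi = np.maximum(p0, p1) + h + px_um
        j0 = max(int(np.floor(lo[0] / px_um)), 0)
        i0 = max(int(np.floor(lo[1] / px_um)), 0)
        j1 = min(int(np.ceil(hi[0] / px_um)) + 1, nx)
        i1 = min(int(np.ceil(hi[1] / px_um)) + 1, ny)
        if j0 >= j1 or i0 >= i1:
            continue
        jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
        px = np.column_stack([jj.ravel() * px_um, ii.ravel() * px_um])
        d = p1 - p0
        L2 = float(d @ d)
        if L2 == 0:
            dist = np.linalg.norm(px - p0, axis=1)
        else:
            t = np.clip((px - p0) @ d / L2, 0.0, 1.0)
            proj = p0[None, :] + t[:, None] * d[None, :]
            dist = np.linalg.norm(px - proj, axis=1)
        out[i0:i1, j0:j1] |= (dist <= h).reshape(ii.shape)
    return out


def rasterize_cristae(
    scene: GroundTruthScene, pixel_size_nm: float, thickness_nm: Optional[float] = None
) -> np.ndarray:
    """Ground-truth binary raster of all cristae at a chosen line thickness.

    Default thickness is the scene's cristae thickness; segmentation tests
    rasterize at the imaging resolution for a like-for-like comparison.
    """
    params = scene.params
    px_um = pixel_size_nm / 1000.0
    th = params.cristae_thickness_nm if thickness_nm is None else thickness_nm
    segs = [s for comp in scene.components for s in comp.cristae]
    return _rasterize_distance(
        _grid_shape(params, px_um), segs, px_um, th / 2000.0
    )


def rasterize_tubules(scene: GroundTruthScene, pixel_size_nm: float) -> np.ndarray:
    """Ground-truth binary raster of the tubule envelopes."""
    px_um = pixel_size_nm / 1000.0
    segs: List[Tuple[np.ndarray, np.ndarray]] = []
    widths: List[float] = []
    for comp in scene.components:
        for tub in comp.tubules:
            ss = _polyline_segments(tub.points)
            segs.extend(ss)
            widths.extend([comp.radius_um] * len(ss))
    return _rasterize_distance(
        _grid_shape(scene.params, px_um), segs, px_um, widths
    )


# ---------------------------------------------------------------------------
# Morphology populations (fragment / intermediate / network mixtures)
# ---------------------------------------------------------------------------


def _max_count(length_um: float, spacing_um: float) -> int:
    return max(int(np.ceil(length_um / spacing_um - 0.5)), 1)


def sample_morphology_population(
    mixture: Sequence[float],
    n: int,
    seed: int,
    rule: ClassificationRule = ClassificationRule(),
    cristae_spacing_um: float = 0.07,
    effective_cluster_spacing_um: float = 0.35,
) -> pd.DataFrame:
    """Draw (length, cristae count) pairs with prescribed class mixture.

    ``mixture`` gives the Class I/II/III fractions.  Lengths come from a
    lognormal base distribution, rejection-sampled into the drawn class's
    admissible region; the count is length / effective cluster spacing plus
    noise, clipped into the class region (cristae occur in clusters, so the
    per-organelle count grows much more slowly than length / 70 nm).
    Returns a DataFrame with ``length_um``, ``n_cristae``, ``true_class``.
    """
    mixture = np.asarray(mixture, dtype=float)
    if mixture.min() < 0 or not np.isclose(mixture.sum(), 1.0):
        raise ParameterError("mixture must be non-negative and sum to 1")
    if np.all(mixture == 0):
        raise ParameterError("at least one class fraction must be positive")
    rng = np.random.default_rng(seed)
    classes = rng.choice(3, size=n, p=mixture)
    lengths = np.empty(n)
    counts = np.empty(n, dtype=int)
    names = np.array(["I", "II", "III"], dtype=object)

    def draw_length(lo: float, hi: float) -> float:
        for _ in range(10000):
            val = rng.lognormal(mean=np.log(3.0), sigma=0.7)
            if lo <= val <= hi:
                return float(val)
        return float(np.clip(rng.uniform(lo, hi), lo, hi))

    for i, cls in enumerate(classes):
        if cls == 0:  # Class I: L < 2.5 and C < 6
            L = draw_length(0.8, rule.length_low_um - 0.05)
            lo, hi = 1, min(rule.cristae_low - 1, _max_count(L, cristae_spacing_um))
        elif cls == 1:  # Class II: (2.5 <= L <= 5 and C <= 12) or (C in 6..12)
            if rng.random() < 0.6:
                L = draw_length(rule.length_low_um, rule.length_high_um)
                lo, hi = 2, rule.cristae_high
            else:
                L = draw_length(1.0, rule.length_low_um - 0.05)
                lo, hi = rule.cristae_low, min(
                    rule.cristae_high, _max_count(L, cristae_spacing_um)
                )
        else:  # Class III: L > 5 (any C) or C > 12
            if rng.random() < 0.6:
                L = draw_length(rule.length_high_um + 0.2, 9.0)
                lo, hi = 3, min(24, _max_count(L, cristae_spacing_um))
            else:
                L = draw_length(1.2, rule.length_high_um)
                lo, hi = rule.cristae_high + 1, min(
                    24, _max_count(L, cristae_spacing_um)
                )
        base = L / effective_cluster_spacing_um + rng.normal(0, 1.5)
        C = int(np.clip(round(base), lo, max(lo, hi)))
        got = classify_mitochondrion(L, C, rule)
        assert got == names[cls], (L, C, got, names[cls])
        lengths[i], counts[i] = L, C

    return pd.DataFrame(
        {"length_um": lengths, "n_cristae": counts, "true_class": names[classes]}
    )


def build_tubule_grid(
    n_tubules: int,
    length_um: float = 5.0,
    pitch_um: float = 3.0,
    diameter_nm: float = 400.0,
    seed: int = 0,
    n_per_field: int = 8,
    rule: ClassificationRule = ClassificationRule(),
) -> List[GroundTruthScene]:
    """Fields of isolated, gently curved tubules on a regular grid.

    Used for distance-law studies: rows are far enough apart that a tip's
    nearest nucleoid is almost surely its own tubule's.
    """
    rng = np.random.default_rng(seed)
    scenes: List[GroundTruthScene] = []
    margin = 1.5
    spacing = 0.07
    for f0 in range(0, n_tubules, n_per_field):
        k_here = min(n_per_field, n_tubules - f0)
        params = SceneParams(
            field_size_um=(length_um + 2 * margin, (k_here - 1) * pitch_um + 2 * margin),
            tubule_diameter_range_nm=(diameter_nm, diameter_nm),
            n_components=k_here,
        )
        comps = []
        for k in range(k_here):
            radius = diameter_nm / 2000.0
            y0 = margin + k * pitch_um
            phase = rng.uniform(0, 2 * np.pi)
            xs = np.arange(0, length_um * 1.2, 0.02)
            ys = 0.15 * np.sin(2 * np.pi * xs / 4.0 + phase)
            pts = np.column_stack([xs + margin, ys + y0])
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            cum = np.concatenate([[0.0], np.cumsum(seg)])
            pts = pts[: max(int(np.searchsorted(cum, length_um)), 2)]
            tub = Tubule(pts)
            cristae = _place_cristae_on_tubule(
                tub, spacing, 0.75 * radius, np.empty((0, 2)), radius
            )
            comps.append(
                TubuleComponent(
                    radius_um=radius, tubules=[tub],
                    branch_points_um=np.empty((0, 2)),
                    tips_um=np.vstack([pts[0], pts[-1]]),
                    cristae=cristae, length_um=tub.length_um,
                    n_cristae=len(cristae),
                    true_class=classify_mitochondrion(
                        tub.length_um, len(cristae), rule
                    ),
                )
            )
        scenes.append(GroundTruthScene(params=params, components=comps))
    return scenes


def build_population_scenes(
    samples: pd.DataFrame,
    seed: int,
    pixel_size_nm: float = 20.0,
    n_per_field: int = 7,
    diameter_range_nm: Tuple[float, float] = (250.0, 550.0),
    rule: ClassificationRule = ClassificationRule(),
) -> List[GroundTruthScene]:
    """Lay a morphology population out as renderable single-tubule scenes.

    Each sampled (length, count) pair becomes one gently curved, unbranched
    tubule on its own row of a field, with exactly ``n_cristae`` cristae
    spread evenly along the centerline; rows are spaced so that mask closing
    cannot merge neighbours.
    """
    rng = np.random.default_rng(seed)
    rows = [samples.iloc[i] for i in range(len(samples))]
    scenes: List[GroundTruthScene] = []
    row_pitch = 1.8
    margin = 1.2
    for f0 in range(0, len(rows), n_per_field):
        chunk = rows[f0 : f0 + n_per_field]
        width = max(float(r.length_um) for r in chunk) + 2 * margin
        height = (len(chunk) - 1) * row_pitch + 2 * margin
        params = SceneParams(
            field_size_um=(width + 0.5, height),
            tubule_diameter_range_nm=diameter_range_nm,
            n_components=len(chunk),
        )
        comps = []
        for k, r in enumerate(chunk):
            L = float(r.length_um)
            n_cr = int(r.n_cristae)
            radius = rng.uniform(*diameter_range_nm) / 2000.0
            y0 = margin + k * row_pitch
            amp = 0.12
            lam = 4.0
            phase = rng.uniform(0, 2 * np.pi)
            # arc-length parameterized gentle sine
            xs = np.arange(0, L * 1.2, 0.02)
            ys = amp * np.sin(2 * np.pi * xs / lam + phase)
            pts = np.column_stack([xs + margin, ys + y0])
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            cum = np.concatenate([[0.0], np.cumsum(seg)])
            stop = int(np.searchsorted(cum, L))
            pts = pts[: max(stop, 2)]
            tub = Tubule(pts)
            Lt = tub.length_um
            pos = (np.arange(n_cr) + 0.5) / n_cr * Lt
            cristae = _place_cristae_on_tubule(
                tub, 0.07, 0.75 * radius, np.empty((0, 2)), radius,
                target_positions=pos,
            )
            comps.append(
                TubuleComponent(
                    radius_um=radius,
                    tubules=[tub],
                    branch_points_um=np.empty((0, 2)),
                    tips_um=np.vstack([pts[0], pts[-1]]),
                    cristae=cristae,
                    length_um=Lt,
                    n_cristae=len(cristae),
                    true_class=classify_mitochondrion(Lt, len(cristae), rule),
                )
            )
        scenes.append(GroundTruthScene(params=params, components=comps))
    return scenes
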