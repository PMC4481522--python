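"""Synthetic valve patterns, culture time series and feature tables.

Three generators provide, with full ground truth and seeded
determinism, the inputs every downstream stage expects:

* ``generate_valve_pattern`` draws an SEM-like valve interior: silica
  ribs radiating from a central hub that split dichotomously as they
  grow outward.  A ``supply`` parameter in [0, 1] sets the probability
  that a rib meeting a neighboring rib fuses with it (cross-linking
  into meshes) rather than terminating.  Low supply yields pure
  tree-like patterns, high supply dense mesh-like ones — the continuum
  expected from diffusion-limited silica deposition at low vs high
  silicon supply.  The growth model is a lattice branching walk with
  fusion, not a physical deposition simulation: it is fast, exactly
  seedable, and spans the same tree-mesh continuum.

* ``generate_population_series`` emulates the density and cell-volume
  output of a Coulter counter over a three-phase batch culture.

* ``generate_feature_table`` draws labeled two-class morphometric
  feature tables from per-class multivariate normals, emulating a
  per-image feature spreadsheet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as draw_line

from .classify import FeatureTable
from .imageprep import RasterImage
from .morphometry import FEATURE_NAMES
from .popdyn import DensitySeries, VolumeDistribution

# ---------------------------------------------------------------------------
# valve patterns
# ---------------------------------------------------------------------------

#: chebyshev clearance (px) enforced between distinct ribs; chosen so the
#: rendered 3-px-wide ribs never touch except at explicit fusion bridges
_CLEARANCE = 4
#: pixels of a tip's own recent path exempt from the clearance check
_TRAIL = 12
#: steps after a split during which siblings grow straight and ignore
#: each other (they start closer than the clearance by construction)
_GRACE = 5

TREE_MAX_SUPPLY = 0.2  # generator metadata: label thresholds on supply
MESH_MIN_SUPPLY = 0.8


@dataclass
class PatternSpec:
    """Parameters of one synthetic valve pattern.

    supply=0 forbids all fusion events, so the resulting skeleton is a
    forest with zero bounded faces; supply=1 fuses every encounter,
    producing a dense mesh.  Same spec + same seed is bit-identical.
    """

    supply: float = 0.5
    radius_px: int = 128
    n_ribs: int = 12
    branch_prob: float = 0.18
    seed: int = 0
    noise_sd: float = 0.0
    pixel_size_um: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 <= self.supply <= 1.0):
            raise ValueError("supply must be in [0, 1]")
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")
        if self.n_ribs < 3:
            raise ValueError("n_ribs must be >= 3")
        if not (0.0 <= self.branch_prob <= 1.0):
            raise ValueError("branch_prob must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


class _Tip:
    __slots__ = ("pos", "ang", "trail", "age", "sibling")

    def __init__(self, pos, ang, trail, sibling=None):
        self.pos = np.asarray(pos, float)
        self.ang = float(ang)
        self.trail = list(trail)
        self.age = 0
        self.sibling = sibling


def _nearest_occupied(occ, p, ignore_sets, radius):
    r, c = p
    r0, c0 = max(r - radius, 0), max(c - radius, 0)
    win = occ[r0 : r + radius + 1, c0 : c + radius + 1]
    hits = np.argwhere(win)
    best, best_d = None, None
    for hr, hc in hits:
        q = (int(hr + r0), int(hc + c0))
        if q == p or any(q in s for s in ignore_sets):
            continue
        d = max(abs(q[0] - r), abs(q[1] - c))
        if best is None or d < best_d:
            best, best_d = q, d
    return best


def generate_valve_pattern(spec: PatternSpec) -> tuple[RasterImage, str]:
    """Grow one valve pattern; returns (image, label).

    The label is "tree" for supply <= 0.2, "mesh" for supply >= 0.8 and
    "mixed" in between — thresholds are generator metadata, reflecting
    that most real patterns are neither purely tree- nor mesh-like.
    The ground-truth silica mask, fusion count and center are stored in
    ``image.meta``.
    """
    rng = np.random.default_rng(spec.seed)
    R = spec.radius_px
    size = 2 * R + 9
    cr = cc = size // 2
    occ = np.zeros((size, size), dtype=bool)

    # central hub: filled disc large enough that rib starting points sit
    # beyond the clearance of their angular neighbors (chebyshev margin)
    sep = 2.0 * math.sin(math.pi / spec.n_ribs)
    r0 = max(12, int(math.ceil((_CLEARANCE + 2.0) * math.sqrt(2.0) / sep)))
    r0 = min(r0, max(R - 4, 2))
    yy, xx = np.ogrid[:size, :size]
    occ[(yy - cr) ** 2 + (xx - cc) ** 2 <= r0**2] = True
    hub = set(map(tuple, np.argwhere(occ)))

    tips: list[_Tip] = []
    for k in range(spec.n_ribs):
        ang = 2.0 * math.pi * k / spec.n_ribs + rng.normal(0.0, 0.05)
        pos = (cr + r0 * math.sin(ang), cc + r0 * math.cos(ang))
        tips.append(_Tip(pos, ang, trail=[]))

    step_len = 2.0
    max_tips = 600
    fusions = 0

    while tips:
        new_tips: list[_Tip] = []
        survivors: list[_Tip] = []
        for tip in tips:
            tip.age += 1
            if tip.age > _GRACE:
                tip.sibling = None
                tip.ang += rng.normal(0.0, 0.18)
            # clamp deviation from the outward radial direction
            radial = math.atan2(tip.pos[0] - cr, tip.pos[1] - cc)
            dev = (tip.ang - radial + math.pi) % (2.0 * math.pi) - math.pi
            if abs(dev) > 1.0:
                tip.ang = radial + math.copysign(1.0, dev)
            new_pos = tip.pos + step_len * np.array(
                [math.sin(tip.ang), math.cos(tip.ang)]
            )
            p0 = (int(round(tip.pos[0])), int(round(tip.pos[1])))
            p1 = (int(round(new_pos[0])), int(round(new_pos[1])))
            rr, cc_ = draw_line(*p0, *p1)
            alive = True
            for pr, pc in zip(rr.tolist(), cc_.tolist()):
                p = (pr, pc)
                if occ[p] or p in hub:
                    continue
                if (pr - cr) ** 2 + (pc - cc) ** 2 > R * R:
                    alive = False
                    break
                ignore_sets = [hub, set(tip.trail[-_TRAIL:])]
                if tip.sibling is not None:
                    ignore_sets.append(set(tip.sibling.trail[-_TRAIL:]))
                q = _nearest_occupied(occ, p, ignore_sets, _CLEARANCE)
                if q is not None:
                    if rng.random() < spec.supply:
                        # fuse: draw a bridge connecting this rib to q
                        br, bc = draw_line(*p, *q)
                        occ[br, bc] = True
                        fusions += 1
                    alive = False
                    break
                occ[p] = True
                tip.trail.append(p)
            if not alive:
                continue
            tip.pos = new_pos
            if (
                tip.age > _GRACE
                and rng.random() < spec.branch_prob
                and len(tips) + len(new_tips) < max_tips
            ):
                delta = rng.uniform(0.35, 0.65)
                a = _Tip(tip.pos, tip.ang + delta, tip.trail[-_TRAIL:])
                b = _Tip(tip.pos, tip.ang - delta, tip.trail[-_TRAIL:])
                a.sibling, b.sibling = b, a
                new_tips.extend([a, b])
            else:
                survivors.append(tip)
        tips = survivors + new_tips

    mask = ndimage.binary_dilation(occ, structure=ndimage.generate_binary_structure(2, 1))
    # fill hairline pinches: sub-resolution (<= 2 px) enclosed background
    # created where diverging rib tubes separate, which are rendering
    # artifacts rather than meshes
    lab, n = ndimage.label(~mask)  # 4-connected background
    if n:
        sizes = np.bincount(lab.ravel())
        border = set(np.unique(np.concatenate(
            [lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]]
        )).tolist())
        for i in range(1, n + 1):
            if i not in border and sizes[i] <= 2:
                mask[lab == i] = True
    img = np.full((size, size), 30.0)
    img[mask] = 200.0
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    if spec.supply <= TREE_MAX_SUPPLY:
        label = "tree"
    elif spec.supply >= MESH_MIN_SUPPLY:
        label = "mesh"
    else:
        label = "mixed"
    meta = {
        "truth_mask": mask,
        "supply": spec.supply,
        "seed": spec.seed,
        "label": label,
        "center": (cr, cc),
        "fusions": fusions,
    }
    return RasterImage(img, spec.pixel_size_um, meta), label


# ---------------------------------------------------------------------------
# population time series
# ---------------------------------------------------------------------------


def _default_sampling() -> np.ndarray:
    # dense early sampling during exponential growth, sparser later
    return np.concatenate([np.arange(0.0, 120.0, 10.0), np.arange(120.0, 361.0, 24.0)])


@dataclass
class PopulationParams:
    """Ground-truth parameters of a simulated batch culture.

    Defaults emulate a culture grown at 14 degrees C: initial density
    0.33e6 cells/mL doubling every 40.9 h, a plateau at 1.16e6 cells/mL
    once silicon is depleted, and regrowth to 1.66x the plateau.  The
    regrowth onset is a synchronized division burst (25% step within
    one sampling interval) followed by slow expansion, which is what
    makes the >20% change-point rule observable.
    """

    d0: float = 0.33e6
    tau_exp: float = 40.9
    t_phase2: float = 74.0
    t_phase3: float = 110.0
    regrowth_factor: float = 1.66
    regrowth_step: float = 0.25
    volume_modes: dict = field(
        default_factory=lambda: {
            # phase -> list of (mean um^3, sd of ln(volume), weight)
            "I": [(45.0, 0.25, 1.0)],
            "II": [(80.0, 0.20, 1.0)],
            "III": [(80.0, 0.20, 0.4), (25.0, 0.30, 0.6)],
        }
    )
    sampling_times: np.ndarray = field(default_factory=_default_sampling)
    obs_noise_cv: float = 0.0
    seed: int = 0
    n_bins: int = 64
    volume_range_um3: tuple[float, float] = (10.0, 300.0)
    dilution_factor: float = 50.0
    analyzed_sample_volume_mL: float = 0.1

    def __post_init__(self) -> None:
        self.sampling_times = np.asarray(self.sampling_times, float)
        if len(self.sampling_times) == 0:
            raise ValueError("sampling_times must be non-empty")
        if not (self.t_phase2 < self.t_phase3):
            raise ValueError("t_phase2 must precede t_phase3")
        if self.d0 <= 0 or self.tau_exp <= 0:
            raise ValueError("d0 and tau_exp must be positive")
        if self.regrowth_factor <= 1.0:
            raise ValueError("regrowth_factor must exceed 1")
        if self.obs_noise_cv < 0:
            raise ValueError("obs_noise_cv must be >= 0")


def true_density(params: PopulationParams, t: np.ndarray | float) -> np.ndarray:
    """Noise-free density trajectory: exponential, plateau, burst + regrowth."""
    t = np.atleast_1d(np.asarray(t, float))
    plateau = params.d0 * 2.0 ** (params.t_phase2 / params.tau_exp)
    out = np.where(
        t < params.t_phase2, params.d0 * 2.0 ** (t / params.tau_exp), plateau
    )
    t_end = float(params.sampling_times[-1])
    post = t >= params.t_phase3
    if t_end > params.t_phase3:
        frac = (t - params.t_phase3) / (t_end - params.t_phase3)
        ramp = (params.regrowth_factor / (1.0 + params.regrowth_step)) ** np.clip(
            frac, 0.0, 1.0
        )
    else:
        ramp = np.ones_like(t)
    out = np.where(post, plateau * (1.0 + params.regrowth_step) * ramp, out)
    return out


def _phase_of(params: PopulationParams, t: float) -> str:
    if t < params.t_phase2:
        return "I"
    if t < params.t_phase3:
        return "II"
    return "III"


def generate_population_series(
    params: PopulationParams,
) -> tuple[DensitySeries, list[VolumeDistribution]]:
    """Simulate a density series plus per-time cell-volume histograms.

    Histogram counts are the expected (real-valued) counts of a
    lognormal mixture scaled so that integrating a noise-free
    distribution recovers the density exactly; observation noise is
    multiplicative with the given CV, applied per time point.
    """
    rng = np.random.default_rng(params.seed)
    t = params.sampling_times
    dens_true = true_density(params, t)
    noise = (
        np.maximum(1.0 + rng.normal(0.0, params.obs_noise_cv, len(t)), 1e-6)
        if params.obs_noise_cv > 0
        else np.ones(len(t))
    )
    dens_obs = dens_true * noise

    lo, hi = params.volume_range_um3
    edges = np.logspace(np.log10(lo), np.log10(hi), params.n_bins + 1)
    mids = np.sqrt(edges[:-1] * edges[1:])
    dists: list[VolumeDistribution] = []
    biovol = np.empty(len(t))
    for i, ti in enumerate(t):
        modes = params.volume_modes[_phase_of(params, float(ti))]
        w = np.zeros(params.n_bins)
        for mean, sdlog, weight in modes:
            z = (np.log(mids) - np.log(mean)) / sdlog
            dens = np.exp(-0.5 * z**2) * np.diff(np.log(edges))
            if dens.sum() > 0:
                w += weight * dens / dens.sum()
        if w.sum() > 0:
            w = w / w.sum()
        total_counts = (
            dens_obs[i] * params.analyzed_sample_volume_mL / params.dilution_factor
        )
        counts = total_counts * w
        dists.append(
            VolumeDistribution(
                float(ti), edges, counts,
                params.dilution_factor, params.analyzed_sample_volume_mL,
            )
        )
        biovol[i] = params.dilution_factor * np.sum(counts * mids) / params.analyzed_sample_volume_mL

    series = DensitySeries(
        t, dens_obs, biovolume=biovol,
        meta={
            "true_tau": params.tau_exp,
            "true_t_phase2": params.t_phase2,
            "true_t_phase3": params.t_phase3,
            "true_d0": params.d0,
        },
    )
    return series, dists


# ---------------------------------------------------------------------------
# labeled feature tables
# ---------------------------------------------------------------------------

#: features that genuinely separate tree- from mesh-like patterns;
#: positive shift = larger in the mesh class
DISCRIMINATIVE_SHIFTS = {
    "n_meshes": +1.0,
    "total_mesh_area": +1.0,
    "mean_mesh_area": +1.0,
    "n_segments": +1.0,
    "total_segment_length": +1.0,
    "n_extremities": -1.0,
    "n_branches": -1.0,
    "total_branch_length": -1.0,
}

_BASE_MEANS = {
    "n_extremities": 60, "n_nodes": 100, "n_junctions": 40,
    "n_master_junctions": 12, "n_segments": 30, "n_master_segments": 10,
    "n_branches": 55, "n_isolated": 3, "total_segment_length": 60.0,
    "total_master_segment_length": 25.0, "total_branch_length": 90.0,
    "total_isolated_length": 5.0, "total_length": 155.0,
    "mean_segment_length": 2.0, "mean_branch_length": 1.6,
    "branching_interval": 4.0, "n_meshes": 25, "total_mesh_area": 6.0,
    "mean_mesh_area": 0.24, "mesh_index": 8.0, "valve_diameter_um": 5.0,
    "rimoportulae_per_area": 0.15,
}


@dataclass
class ClassTableSpec:
    """Specification for a synthetic labeled two-class feature table."""

    n_per_class: int = 60
    separation: float = 4.0
    feature_means: dict[str, np.ndarray] | None = None
    feature_sds: dict[str, np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")


def _default_class_params(spec: ClassTableSpec):
    base = np.array([_BASE_MEANS[f] for f in FEATURE_NAMES], float)
    sds = 0.15 * np.abs(base)
    means = {"tree": base.copy(), "mesh": base.copy()}
    for fname, sign in DISCRIMINATIVE_SHIFTS.items():
        j = FEATURE_NAMES.index(fname)
        means["mesh"][j] = base[j] + sign * spec.separation * sds[j]
    return means, {"tree": sds, "mesh": sds.copy()}


def generate_feature_table(spec: ClassTableSpec) -> FeatureTable:
    """Draw a labeled tree/mesh feature table from per-class normals.

    Count, length and area features are truncated at zero.  With
    separation 0 the classes are exchangeable; at separation >= 4
    pooled SDs they are essentially linearly separable.
    """
    if spec.feature_means is not None:
        means = {k: np.asarray(v, float) for k, v in spec.feature_means.items()}
    else:
        means = None
    if spec.feature_sds is not None:
        sds = {k: np.asarray(v, float) for k, v in spec.feature_sds.items()}
    else:
        sds = None
    if means is None or sds is None:
        dmeans, dsds = _default_class_params(spec)
        means = means or dmeans
        sds = sds or dsds
    for cls, sd in sds.items():
        if np.any(sd <= 0):
            raise ValueError(f"sds for class {cls!r} must be positive")

    rng = np.random.default_rng(spec.seed)
    rows, labels, index = [], [], []
    for cls in ("tree", "mesh"):
        x = rng.normal(
            means[cls], sds[cls], size=(spec.n_per_class, len(FEATURE_NAMES))
        )
        x = np.clip(x, 0.0, None)  # counts/lengths/areas cannot be negative
        rows.append(x)
        labels += [cls] * spec.n_per_class
        index += [f"{cls}_{i:03d}" for i in range(spec.n_per_class)]
    data = pd.DataFrame(np.vstack(rows), columns=FEATURE_NAMES, index=index)
    return FeatureTable(data, labels=pd.Series(labels, index=index))
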