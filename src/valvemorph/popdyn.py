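"""Batch-culture population dynamics from cell-volume distributions.

A Coulter-counter style volume distribution integrates to cell density
and biovolume.  Density time series of a silicon-limited batch culture
show three phases: (I) exponential growth d0 * 2^(t/tau) while silicon
is replete, (II) a density plateau after Si depletion during which the
synchronized cells elongate, and (III) delayed regrowth, flagged when
the density change between successive measurements exceeds 20%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class VolumeDistribution:
    """One cell-volume histogram (log-spaced bins, um^3) at one time."""

    time_h: float
    bin_edges_um3: np.ndarray  # length n_bins + 1, strictly increasing
    counts: np.ndarray  # length n_bins, >= 0
    dilution_factor: float = 50.0
    analyzed_sample_volume_mL: float = 0.1

    def __post_init__(self) -> None:
        self.bin_edges_um3 = np.asarray(self.bin_edges_um3, float)
        self.counts = np.asarray(self.counts, float)
        if np.any(np.diff(self.bin_edges_um3) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.counts) != len(self.bin_edges_um3) - 1:
            raise ValueError("counts length must match bins")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    def bin_midpoints(self) -> np.ndarray:
        """Geometric midpoints, appropriate for log-spaced bins."""
        return np.sqrt(self.bin_edges_um3[:-1] * self.bin_edges_um3[1:])


@dataclass
class DensitySeries:
    """Cell density (and optional biovolume) over time for one culture."""

    times_h: np.ndarray
    density: np.ndarray  # cells / mL
    biovolume: np.ndarray | None = None  # um^3 / mL
    replicate: str = "r1"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, float)
        self.density = np.asarray(self.density, float)
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.density) != len(self.times_h):
            raise ValueError("density length must match times")
        if np.any(self.density < 0):
            raise ValueError("densities must be >= 0")
        if self.biovolume is not None:
            self.biovolume = np.asarray(self.biovolume, float)


@dataclass
class PhaseSummary:
    """Growth-phase characteristics of one culture.

    tau_exp_h is the doubling timescale of the initial exponential
    phase; d1 the average density over the plateau (phase II); d2 the
    final density (phase III).
    """

    d0: float
    tau_exp_h: float
    tau_ci_h: float
    t_phase2_h: float
    t_phase3_h: float | None
    d1: float
    d1_sd: float
    d2: float
    d2_sd: float = 0.0

    @property
    def ratio_d1_d0(self) -> float:
        return self.d1 / self.d0

    @property
    def ratio_d2_d1(self) -> float:
        return self.d2 / self.d1


def density_from_distribution(vd: VolumeDistribution) -> float:
    """Cell density (cells/mL) by integrating the volume distribution.

    density = dilution * total counts / analyzed sample volume.
    """
    if vd.analyzed_sample_volume_mL <= 0:
        raise ValueError("analyzed sample volume must be positive")
    return float(vd.dilution_factor * vd.counts.sum() / vd.analyzed_sample_volume_mL)


def biovolume_from_distribution(vd: VolumeDistribution) -> float:
    """Total cell volume per mL (um^3/mL), using geometric bin midpoints."""
    if vd.analyzed_sample_volume_mL <= 0:
        raise ValueError("analyzed sample volume must be positive")
    total = float(np.sum(vd.counts * vd.bin_midpoints()))
    return vd.dilution_factor * total / vd.analyzed_sample_volume_mL


def fit_doubling_timescale(
    s: DensitySeries, fit_window_h: float | None = None
) -> tuple[float, float, float]:
    """Fit d0 * 2^(t/tau) to the initial growth; return (tau, tau_ci, d0_hat).

    The fit is ordinary least squares of log2(density) on time, which is
    exact for multiplicative noise and gives a closed-form standard
    error; tau = 1/slope and its CI follows by the delta method.
    ``fit_window_h`` restricts the fit to t <= window; when None the
    window ends where the per-interval relative growth rate first drops
    below 10% of the initial rate (the estimated plateau onset).
    """
    t, d = s.times_h, s.density
    if fit_window_h is not None:
        m = t <= fit_window_h
        if m.sum() < 3:
            raise ValueError("need >= 3 points in the fit window")
    else:
        m = t < _plateau_onset(s, rel_tol=0.10)
        if m.sum() < 3:  # plateau within the first samples: take what exists
            m = np.zeros(len(t), bool)
            m[: min(3, len(t))] = True
    if m.sum() < 3:
        raise ValueError("need >= 3 points in the fit window")
    if np.any(d[m] <= 0):
        raise ValueError("non-positive densities in fit window")
    res = stats.linregress(t[m], np.log2(d[m]))
    if res.slope <= 0:
        raise ValueError("no growth in fit window")
    tau = 1.0 / res.slope
    tau_ci = res.stderr / res.slope**2  # delta method: d(1/x) = -dx/x^2
    d0_hat = float(2.0**res.intercept)
    return float(tau), float(tau_ci), d0_hat


def _interval_rates(s: DensitySeries) -> np.ndarray:
    """Per-interval relative growth rate on median-of-3 smoothed density.

    The 3-point running median removes single-point counting noise
    without lagging a monotone trend (the median of monotone triples is
    the center point), so noiseless series are unaffected while noisy
    plateaus produce near-zero rates.
    """
    t, d = s.times_h, s.density
    pad = np.concatenate([d[:1], d, d[-1:]])
    dm = np.median(np.column_stack([pad[:-2], pad[1:-1], pad[2:]]), axis=1)
    dd = np.diff(dm)
    dt = np.diff(t)
    base = np.maximum(dm[:-1], 1e-300)
    return np.abs(dd) / (base * dt)


def _phase1_rate(s: DensitySeries) -> float:
    """Relative growth rate ln2/tau (per h) fitted on the first 4 points."""
    t, d = s.times_h[:4], s.density[:4]
    if np.any(d <= 0):
        return 0.0
    res = stats.linregress(t, np.log2(d))
    return max(float(res.slope) * math.log(2.0), 0.0)


def segment_growth_phases(
    s: DensitySeries,
    plateau_tol: float | None = None,
    regrowth_frac: float = 0.20,
) -> tuple[float, float | None]:
    """Locate the onsets of phase II (plateau) and phase III (regrowth).

    Phase II starts at the first time where the per-interval relative
    growth rate falls below ``plateau_tol`` (default: 10% of the phase-I
    rate ln2/tau fitted on the first measurements).  Phase III starts at
    the first subsequent measurement whose relative density step
    (d_{i+1} - d_i)/d_i exceeds ``regrowth_frac``; if none does, phase
    III is absent (None).
    """
    if len(s.times_h) < 4:
        raise ValueError("need at least 4 time points to segment phases")
    rates = _interval_rates(s)
    if plateau_tol is None:
        r1 = _phase1_rate(s)
        if r1 <= 1e-15:
            i2 = 0  # never grew: the plateau starts immediately
        else:
            below = np.nonzero(rates < 0.10 * r1)[0]
            if len(below) == 0:
                raise ValueError("no plateau found: growth never slows below tolerance")
            i2 = int(below[0])
    else:
        below = np.nonzero(rates < plateau_tol)[0]
        if len(below) == 0:
            raise ValueError("no plateau found: growth never slows below tolerance")
        i2 = int(below[0])
    t_phase2 = float(s.times_h[i2])

    d = s.density
    t_phase3 = None
    for i in range(i2, len(d) - 1):
        if d[i] > 0 and (d[i + 1] - d[i]) / d[i] > regrowth_frac:
            t_phase3 = float(s.times_h[i + 1])
            break
    return t_phase2, t_phase3


def _plateau_onset(s: DensitySeries, rel_tol: float) -> float:
    rates = _interval_rates(s)
    r1 = _phase1_rate(s)
    if r1 <= 1e-15:
        return float(s.times_h[0])
    below = np.nonzero(rates < rel_tol * r1)[0]
    if len(below) == 0:
        return float(s.times_h[-1])
    return float(s.times_h[int(below[0])])


def summarize_phases(
    s: DensitySeries,
    seg: tuple[float, float | None] | None = None,
    fit_window_h: float | None = None,
) -> PhaseSummary:
    """Compute the phase characteristics of one density series.

    d1 is the mean (+- sd) density over [t_phase2, t_phase3); d2 the
    density at the last measurement.
    """
    if seg is None:
        seg = segment_growth_phases(s)
    t_phase2, t_phase3 = seg
    tau, tau_ci, d0_hat = fit_doubling_timescale(s, fit_window_h)
    t, d = s.times_h, s.density
    upper = t_phase3 if t_phase3 is not None else np.inf
    m2 = (t >= t_phase2) & (t < upper)
    if not m2.any():
        raise ValueError("empty phase II")
    d1 = float(d[m2].mean())
    d1_sd = float(d[m2].std(ddof=1)) if m2.sum() > 1 else 0.0
    return PhaseSummary(
        d0=float(d[0]),
        tau_exp_h=tau,
        tau_ci_h=tau_ci,
        t_phase2_h=t_phase2,
        t_phase3_h=t_phase3,
        d1=d1,
        d1_sd=d1_sd,
        d2=float(d[-1]),
    )


def summarize_replicates(summaries: list[PhaseSummary]) -> dict:
    """Mean +- sd of the phase characteristics across replicate cultures."""
    def ms(vals):
        v = np.asarray([x for x in vals if x is not None], float)
        return (float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0)

    out = {}
    for name in ("tau_exp_h", "t_phase2_h", "t_phase3_h", "d1", "d2"):
        out[name] = ms([getattr(x, name) for x in summaries])
    out["ratio_d1_d0"] = ms([x.ratio_d1_d0 for x in summaries])
    out["ratio_d2_d1"] = ms([x.ratio_d2_d1 for x in summaries])
    return out
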