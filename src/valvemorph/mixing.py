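"""Valve-inheritance mixing model for population meshiness.

At division each daughter diatom keeps one parental valve and
synthesizes one new valve.  Valves made while silicon is replete
(phase I) are mesh-like with weight ``mesh_p1`` and — under the
assumption that live cells neither dissolve nor remodel silica —
retain that pattern; valves made after Si depletion are tree-like,
with mesh weight ``1 - mesh_p1``.  The meshiness of the final
population is therefore a weighted average over old and new valves:

    meshiness = [d_p1 * mesh_p1 + (d_p2p3 - d_p1) * (1 - mesh_p1)] / d_p2p3

where d_p1 and d_p2p3 are the culture densities at the early and late
observation times.  Valve counts carry a factor of two relative to
cell counts which cancels in the average; the stochastic simulator in
this module works in valves and serves as an independent check of that
cancellation and of the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MixingInputs:
    """Inputs of the mixing model for one condition.

    ``mesh_p2p3`` is always derived as ``1 - mesh_p1``, never stored.
    """

    mesh_p1: float
    d_p1: float
    d_p2p3: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mesh_p1 <= 1.0):
            raise ValueError("mesh_p1 must be in [0, 1]")
        if self.d_p1 <= 0:
            raise ValueError("d_p1 must be positive")
        if self.d_p2p3 < self.d_p1:
            raise ValueError("d_p2p3 must be >= d_p1 (no cell death modeled)")

    @property
    def mesh_p2p3(self) -> float:
        return 1.0 - self.mesh_p1


def predict_population_meshiness(inputs: MixingInputs) -> float:
    """Closed-form weighted-average meshiness of the final population."""
    w_old = inputs.d_p1 / inputs.d_p2p3
    return w_old * inputs.mesh_p1 + (1.0 - w_old) * inputs.mesh_p2p3


@dataclass
class InheritanceSimConfig:
    """Configuration of the stochastic valve-inheritance simulation.

    ``density_schedule`` is the target density trajectory (arbitrary
    units, non-decreasing); the initial population of ``n0`` cells is
    scaled to its first entry, and at each subsequent entry a random
    subset of cells divides so the population tracks the schedule.
    """

    n0: int = 10_000
    density_schedule: np.ndarray = field(default_factory=lambda: np.array([1.0, 2.0]))
    mesh_p1: float = 0.8
    seed: int = 0
    replicates: int = 20

    def __post_init__(self) -> None:
        self.density_schedule = np.asarray(self.density_schedule, float)
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if np.any(np.diff(self.density_schedule) < 0):
            raise ValueError("density schedule must be non-decreasing (no death modeled)")
        if not (0.0 <= self.mesh_p1 <= 1.0):
            raise ValueError("mesh_p1 must be in [0, 1]")


def simulate_valve_inheritance(cfg: InheritanceSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Simulate valve inheritance; returns (mean trajectory, SE).

    Every initial cell starts with two phase-I valves of meshiness
    ``mesh_p1``.  When a cell divides, each daughter inherits one of
    the parental valves and synthesizes one new valve of meshiness
    ``1 - mesh_p1``.  Population meshiness at each schedule point is
    the mean meshiness over all live cells' valves.  Total valves are
    always twice the cell count, and new valves created equal twice
    the number of divisions — bookkeeping the closed form relies on.
    """
    rng = np.random.default_rng(cfg.seed)
    sched = cfg.density_schedule / cfg.density_schedule[0]
    targets = np.round(cfg.n0 * sched).astype(int)
    traj = np.empty((cfg.replicates, len(targets)))
    for rep in range(cfg.replicates):
        # per-cell valve meshiness; column 0/1 = the two valves
        valves = np.full((cfg.n0, 2), cfg.mesh_p1, float)
        new_mesh = 1.0 - cfg.mesh_p1
        for j, target in enumerate(targets):
            # each cell divides at most once per schedule step, with the
            # probability that tracks the target density (binomial, so
            # replicates genuinely vary around the closed form)
            while valves.shape[0] < target:
                n = valves.shape[0]
                p = min(1.0, target / n - 1.0)
                n_div = int(rng.binomial(n, p)) if p < 1.0 else n
                if n_div == 0:
                    break
                idx = rng.choice(n, size=n_div, replace=False)
                mothers = valves[idx]
                keep = np.ones(n, bool)
                keep[idx] = False
                daughters_a = np.column_stack(
                    [mothers[:, 0], np.full(n_div, new_mesh)]
                )
                daughters_b = np.column_stack(
                    [mothers[:, 1], np.full(n_div, new_mesh)]
                )
                valves = np.vstack([valves[keep], daughters_a, daughters_b])
                if p < 1.0:
                    break
            traj[rep, j] = valves.mean()
    mean = traj.mean(axis=0)
    se = (
        traj.std(axis=0, ddof=1) / np.sqrt(cfg.replicates)
        if cfg.replicates > 1
        else np.zeros(len(targets))
    )
    return mean, se
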