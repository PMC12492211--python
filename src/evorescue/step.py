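"""Step-change model of evolutionary rescue under an abrupt environmental shift.

The environment shifts abruptly to a constant harsh state (here: extreme
early snowmelt imposing drought), dropping mean absolute fitness to W0 < 1.
A single quantitative trait (SLA, cm^2/g) is under constant directional
selection S (raw differential) and responds by the breeder's equation, so the
cumulative change after t generations is ``delta_z_t = t * h2 * S``.  Fitness
recovers in proportion to the trait change,

    W_t = W0 * max(0, 1 + (b/v) * delta_z_t),
    N_{t+1} = W_t * N_t,

where b is the slope of absolute fitness on the raw trait and v the mean
fitness, so b/v is the relative fitness change per unit of trait.  Generation
1 carries the starting population N1.  The population is functionally
extinct once N falls below the extinction threshold (default 2 individuals,
as the species is self-incompatible).

Demographic stochasticity replaces the deterministic update by a Poisson
draw, N_{t+1} ~ Poisson(N_t * W_t): each individual independently leaves a
Poisson(W_t) number of descendants.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .trajectory import RescueOutcome, Trajectory, classify_outcome

__all__ = [
    "StepParams",
    "StepReplicates",
    "SweepGrid",
    "run_step_model",
    "run_step_replicates",
    "sweep_parameter_space",
]

#: Default trait scale (cm^2/g per SD) linking the standardized differential
#: S' = 0.23 to the raw differential S = -5.866 of the reference
#: parameterization: one phenotypic SD of SLA.
DEFAULT_TRAIT_SD = 5.866 / 0.23


@dataclass(frozen=True)
class StepParams:
    """Parameters of the step-change model.

    Defaults are the reference parameterization for *Ipomopsis*: mean
    absolute fitness after the shift W0 = 0.88, mean survival v = 0.554,
    slope of absolute survival on raw SLA b = -0.0034 (so b/v rounds to
    -0.0061), raw selection differential S = -5.866 cm^2/g (the strongest
    observed year, S' = -0.23), heritability 0.10, starting population 200.

    ``b_over_v`` defaults to the rounded -0.0061; pass ``b_over_v=None`` to
    use the exact ratio b/v instead.
    """

    w0: float = 0.88
    v: float = 0.554
    b: float = -0.0034
    b_over_v: Optional[float] = -0.0061
    s_raw: float = -5.866
    h2: float = 0.10
    n1: float = 200.0
    extinction_threshold: float = 2.0
    max_generations: int = 75
    trait_sd: float = DEFAULT_TRAIT_SD

    def __post_init__(self) -> None:
        if self.w0 < 0:
            raise ValueError("w0 must be >= 0")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if self.n1 <= 0:
            raise ValueError("n1 must be positive")
        if self.extinction_threshold < 0:
            raise ValueError("extinction_threshold must be >= 0")
        if self.trait_sd <= 0:
            raise ValueError("trait_sd must be positive")

    @property
    def resolved_b_over_v(self) -> float:
        """b/v actually used: the explicit value, or b divided by v."""
        if self.b_over_v is not None:
            return self.b_over_v
        return self.b / self.v

    @property
    def delta_z_per_generation(self) -> float:
        """Per-generation breeder's-equation response h2 * S (cm^2/g)."""
        return self.h2 * self.s_raw

    def with_sprime(self, sprime: float) -> "StepParams":
        """Parameters with the raw differential set from a standardized one.

        Negative (adaptive, SLA-lowering) selection of standardized magnitude
        ``sprime`` maps to ``s_raw = -sprime * trait_sd``.
        """
        return replace(self, s_raw=-abs(sprime) * self.trait_sd)


def _fitness(params: StepParams, delta_z: float) -> float:
    bracket = 1.0 + params.resolved_b_over_v * delta_z
    return params.w0 * max(0.0, bracket)


def run_step_model(params: StepParams) -> Trajectory:
    """Deterministic step-change trajectory.

    Iterates until ``max_generations`` or functional extinction, whichever
    comes first; the extinction generation is recorded in the trajectory.
    """
    rows = []
    n = float(params.n1)
    for t in range(1, params.max_generations + 1):
        delta_z = t * params.h2 * params.s_raw
        w = _fitness(params, delta_z)
        rows.append((t, delta_z, 0.0, w, n))
        if n < params.extinction_threshold:
            break
        n = w * n
    data = pd.DataFrame(
        rows, columns=["generation", "delta_z", "plastic_shift", "w_mean", "n"]
    )
    return Trajectory(data, params.extinction_threshold, params={"model": "step", "w0": params.w0})


def _run_step_stochastic(params: StepParams, rng: np.random.Generator) -> Trajectory:
    rows = []
    n = int(round(params.n1))
    for t in range(1, params.max_generations + 1):
        delta_z = t * params.h2 * params.s_raw
        w = _fitness(params, delta_z)
        rows.append((t, delta_z, 0.0, w, n))
        if n < params.extinction_threshold:
            break
        lam = n * w
        # Poisson sampling is pointless (and can overflow) at huge means;
        # relative fluctuation there is < 1e-4.
        n = int(rng.poisson(lam)) if lam < 1e8 else int(round(lam))
    data = pd.DataFrame(
        rows, columns=["generation", "delta_z", "plastic_shift", "w_mean", "n"]
    )
    return Trajectory(data, params.extinction_threshold, params={"model": "step", "w0": params.w0})


@dataclass(frozen=True)
class StepReplicates:
    """Outcomes of seeded stochastic replicates of the step model."""

    outcomes: List[RescueOutcome]
    trajectories: List[Trajectory]

    @property
    def rescued_fraction(self) -> float:
        return float(np.mean([o.rescued for o in self.outcomes]))


def run_step_replicates(
    params: StepParams,
    n_reps: int,
    seed: int,
    horizon: Optional[int] = None,
    keep_trajectories: bool = False,
) -> StepReplicates:
    """Run seeded Poisson-branching replicates of the step model.

    Each replicate gets an independent generator spawned from the root seed,
    so results do not depend on ``n_reps`` ordering.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    horizon = params.max_generations if horizon is None else horizon
    outcomes: List[RescueOutcome] = []
    trajs: List[Trajectory] = []
    for child in np.random.SeedSequence(seed).spawn(n_reps):
        traj = _run_step_stochastic(params, np.random.default_rng(child))
        outcomes.append(classify_outcome(traj, horizon=horizon))
        if keep_trajectories:
            trajs.append(traj)
    return StepReplicates(outcomes, trajs)


@dataclass(frozen=True)
class SweepGrid:
    """Rescue classification over a heritability x selection grid.

    ``values[i, j]`` is the outcome for ``h2_grid[i]`` and ``sprime_grid[j]``:
    1.0/0.0 rescued/extinct in deterministic mode, or the rescued fraction of
    replicates in stochastic mode.
    """

    h2_grid: np.ndarray
    sprime_grid: np.ndarray
    values: np.ndarray
    mode: str
    reps: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.h2_grid, name="h2"),
            columns=pd.Index(self.sprime_grid, name="sprime"),
        )


def sweep_parameter_space(
    base: StepParams,
    h2_grid: Sequence[float],
    sprime_grid: Sequence[float],
    mode: str = "deterministic",
    n_reps: int = 10,
    seed: Optional[int] = None,
    horizon: int = 75,
) -> SweepGrid:
    """Sweep (h2, S') over a grid and classify rescue by ``horizon``.

    Standardized differentials S' are magnitudes; each maps to
    ``s_raw = -S' * trait_sd``.  Grids must be strictly increasing.
    """
    h2s = np.asarray(h2_grid, dtype=float)
    sps = np.asarray(sprime_grid, dtype=float)
    for grid, name in ((h2s, "h2_grid"), (sps, "sprime_grid")):
        if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
            raise ValueError(f"{name} must be a non-empty strictly increasing 1-D grid")
    if mode not in ("deterministic", "stochastic"):
        raise ValueError("mode must be 'deterministic' or 'stochastic'")
    if mode == "stochastic" and seed is None:
        raise ValueError("stochastic sweeps require a seed")
    values = np.empty((h2s.size, sps.size))
    base = replace(base, max_generations=max(base.max_generations, horizon))
    for i, h2 in enumerate(h2s):
        for j, sp in enumerate(sps):
            params = replace(base.with_sprime(sp), h2=float(h2))
            if mode == "deterministic":
                out = classify_outcome(run_step_model(params), horizon=horizon)
                values[i, j] = 1.0 if out.rescued else 0.0
            else:
                cell_seed = np.random.SeedSequence([seed, i, j]).generate_state(1)[0]
                reps = run_step_replicates(params, n_reps, int(cell_seed), horizon)
                values[i, j] = reps.rescued_fraction
    return SweepGrid(h2s, sps, values, mode, n_reps if mode == "stochastic" else 1)
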