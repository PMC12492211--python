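"""Fisher fundamental-theorem bound on adaptation, and realized rates.

Fisher's fundamental theorem gives an upper bound on the per-generation
increase of mean absolute fitness from all heritable variation:

    W_{t+1} <= W_t + V_A(W) / W_t,

with V_A(W) the additive genetic variance in fitness.  The fractional bound
V_A(W)/W^2 equals the squared additive genetic coefficient of variation
CV_A^2.  Comparing that with the *realized* fractional fitness gain of a
single-trait trajectory shows how much of the adaptive potential the one
trait captures.
"""

from __future__ import annotations

from typing import Optional

from .step import StepParams
from .trajectory import Trajectory

__all__ = [
    "fisher_next_fitness",
    "va_from_cv",
    "realized_adaptation_rate",
    "step_adaptation_rate",
]


def fisher_next_fitness(w_mean: float, va_w: float) -> float:
    """Upper bound on next-generation mean fitness, W + V_A(W)/W."""
    if w_mean <= 0:
        raise ValueError("w_mean must be positive")
    if va_w < 0:
        raise ValueError("va_w must be >= 0")
    return w_mean + va_w / w_mean


def va_from_cv(cva: float, w_mean: float) -> float:
    """Additive genetic variance in fitness from its coefficient of variation.

    CV_A is dimensionless (e.g. 0.26); V_A(W) = (CV_A * W)^2.  Which mean
    fitness to scale by is ambiguous in general, so it is an explicit
    argument.
    """
    if cva < 0:
        raise ValueError("cva must be >= 0")
    return (cva * w_mean) ** 2


def realized_adaptation_rate(
    traj: Trajectory, step: int, baseline: Optional[Trajectory] = None
) -> float:
    """Fractional fitness increase attributable to evolution at a generation.

    Computed as (W_evolution - W_baseline) / W_baseline at generation
    ``step``.  Step-model trajectories carry their own flat no-evolution
    baseline W0; for any other model pass the matching no-evolution run as
    ``baseline``.
    """
    row = traj.data.loc[traj.data["generation"] == step]
    if row.empty:
        raise ValueError(f"generation {step} not in trajectory")
    w_evo = float(row["w_mean"].iloc[0])
    if baseline is not None:
        base_row = baseline.data.loc[baseline.data["generation"] == step]
        if base_row.empty:
            raise ValueError(f"generation {step} not in baseline trajectory")
        w_base = float(base_row["w_mean"].iloc[0])
    elif "w0" in traj.params:
        w_base = float(traj.params["w0"])
    else:
        raise ValueError("a baseline trajectory is required for this model")
    if w_base <= 0:
        raise ValueError("baseline fitness is non-positive at this step")
    return w_evo / w_base - 1.0


def step_adaptation_rate(params: StepParams, generation: int) -> float:
    """Closed-form realized rate for the step model: (b/v) * t * h2 * S.

    Equals (W_t with evolution - W0) / W0 as long as the fitness bracket has
    not hit the zero floor (once it has, the rate saturates at -1).
    """
    if generation < 1:
        raise ValueError("generation must be >= 1")
    dz = generation * params.h2 * params.s_raw
    bracket = 1.0 + params.resolved_b_over_v * dz
    if bracket <= 0:
        return -1.0
    return params.resolved_b_over_v * dz
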