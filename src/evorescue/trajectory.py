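"""Per-generation / per-year trajectory records and rescue classification.

Both population models (the abrupt step-change model and the gradual
snowmelt-trend model) report their dynamics as a :class:`Trajectory`: one row
per recorded time point carrying the cumulative genetic trait change, any
plastic trait shift, the realized mean absolute fitness of the generation
whose update happened at that time point, and the population size.  A
population is *functionally extinct* once its size falls below the
extinction threshold (2 individuals by default: the species is
self-incompatible, so a single survivor cannot reproduce).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "RescueOutcome", "classify_outcome"]


@dataclass
class Trajectory:
    """Time-ordered record of a single model run.

    ``data`` has one row per generation (step model) or per calendar year
    (gradual model).  Required columns: ``generation``, ``delta_z`` (cumulative
    genetic change, cm^2/g), ``plastic_shift`` (cm^2/g), ``w_mean`` (mean
    absolute fitness applied at that row's update; NaN for years without a
    generation turnover) and ``n`` (population size; real-valued for
    deterministic runs, integer-valued under demographic stochasticity).
    Gradual-model trajectories additionally carry ``year`` and
    ``snowmelt_day``.
    """

    data: pd.DataFrame
    extinction_threshold: float = 2.0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"generation", "delta_z", "plastic_shift", "w_mean", "n"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"trajectory missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> np.ndarray:
        return self.data["n"].to_numpy(dtype=float)

    @property
    def generations(self) -> np.ndarray:
        return self.data["generation"].to_numpy()

    def _generation_rows(self) -> pd.DataFrame:
        """Rows at which a generation's size is evaluated.

        Gradual-model trajectories record every calendar year; extinction is
        defined on generation boundaries (``is_generation`` column).  Step
        trajectories are per-generation already.
        """
        if "is_generation" in self.data.columns:
            return self.data.loc[self.data["is_generation"].astype(bool)]
        return self.data

    def extinction_step(self) -> Optional[int]:
        """First generation index with N below the extinction threshold."""
        rows = self._generation_rows()
        below = rows.loc[rows["n"] < self.extinction_threshold]
        if below.empty:
            return None
        return int(below["generation"].iloc[0])

    def extinction_year(self) -> Optional[int]:
        """Calendar year of functional extinction (gradual model only)."""
        if "year" not in self.data.columns:
            raise ValueError("trajectory has no calendar-year column")
        rows = self._generation_rows()
        below = rows.loc[rows["n"] < self.extinction_threshold]
        if below.empty:
            return None
        return int(below["year"].iloc[0])


@dataclass(frozen=True)
class RescueOutcome:
    """Extinction-vs-rescue classification of one trajectory."""

    status: str  # "rescued" | "extinct"
    extinction_step: Optional[int]
    min_n: float
    min_n_steps: Tuple[int, int]

    @property
    def rescued(self) -> bool:
        return self.status == "rescued"


def classify_outcome(
    traj: Trajectory,
    horizon: Optional[int] = None,
    threshold: Optional[float] = None,
) -> RescueOutcome:
    """Classify a trajectory as rescued or extinct within a horizon.

    The population is extinct iff N dropped below ``threshold`` at or before
    generation ``horizon`` (default: the whole trajectory).  ``min_n_steps``
    is the first and last generation whose N rounds to the same integer as
    the minimum — the "bottom" of the population dip.
    """
    if len(traj) == 0:
        raise ValueError("cannot classify an empty trajectory")
    thr = traj.extinction_threshold if threshold is None else threshold
    gen_rows = traj._generation_rows()
    if horizon is not None:
        gen_rows = gen_rows.loc[gen_rows["generation"] <= horizon]
    n = gen_rows["n"].to_numpy(dtype=float)
    gens = gen_rows["generation"].to_numpy()
    below = np.nonzero(n < thr)[0]
    min_n = float(n.min())
    at_min = gens[np.round(n) == np.round(min_n)]
    span = (int(at_min.min()), int(at_min.max()))
    if below.size:
        return RescueOutcome("extinct", int(gens[below[0]]), min_n, span)
    return RescueOutcome("rescued", None, min_n, span)
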