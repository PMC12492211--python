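"""Gradual environmental change model: snowmelt-trend-driven rescue dynamics.

Spring snowmelt at the reference climate station advances linearly,
``d(t) = 539.2 - 0.20 t`` days-since-January-1 for calendar year t, with
observed residual scatter of 11.4 days around the trend.  Early snowmelt
imposes drought: baseline mean absolute fitness in the absence of evolution
is a quadratic in the snowmelt day, W0(d), fit to long-term demographic
projections.  Directional selection on SLA also tracks snowmelt,
S(d) = a0 + a1*d (raw, cm^2/g), as does the slope of fitness on the trait,
b(d) = e0 + e1*d.

Generations are discrete with a 5-year generation time, so the yearly
breeder's-equation increment is h2*S(d_t)/5.  Once per generation the
population is updated at the parent generation's year:

    W = W0(d) * max(0, 1 + (b(d + b_day_offset) / W0(d)) * displacement)
    N <- N * W          (or Poisson(N * W) under demographic stochasticity)

where ``displacement`` is the total trait displacement: the cumulative
genetic change plus, when plasticity is on, the accumulated plastic shift
1.323 * (d_t - d_first) cm^2/g (the telescoped sum of year-over-year
snowmelt differences).

``b_day_offset`` reflects that the yearly fitness-slope estimates are
referenced to snowmelt observed at the study site itself, which melts out
later than the reference station (hybrid site +17 d, *I. aggregata* site
+6 d), while the W0 quadratics and the S(d) lines are referenced to the
station day.  See docs/methods.md for the calibration argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .trajectory import Trajectory

__all__ = [
    "SnowmeltModel",
    "GradualSiteParams",
    "hybrid_params",
    "aggregata_params",
    "snowmelt_series",
    "selection_at_day",
    "baseline_fitness_at_day",
    "plastic_shift",
    "run_gradual_model",
    "rescue_probability",
    "RescueProbability",
]


@dataclass(frozen=True)
class SnowmeltModel:
    """Linear snowmelt trend with Gaussian residuals.

    ``day(t) = intercept + slope * t`` for calendar year t; stochastic series
    add Normal(0, residual_sd) residuals.  ``site_offsets`` are mean
    differences of site-observed snowmelt from the reference station, in
    days (used for site-referenced regression lines and sensitivity plots;
    the dynamic models draw the station-day series).
    """

    intercept: float = 539.2
    slope: float = -0.20
    residual_sd: float = 11.4
    site_offsets: Dict[str, float] = field(
        default_factory=lambda: {"agg": 6.0, "hyb": 17.0, "VF": -3.0}
    )

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")

    def day(self, year: float) -> float:
        """Trend-predicted snowmelt day for a calendar year."""
        return self.intercept + self.slope * year


def snowmelt_series(
    model: SnowmeltModel,
    start_year: int,
    n_years: int,
    stochastic: bool = False,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Snowmelt days for ``n_years`` consecutive years from ``start_year``.

    Deterministic series follow the trend exactly; stochastic series draw
    independent untruncated Normal(trend, residual_sd) values, reproducible
    from ``seed`` (or an explicit ``rng``).
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    years = np.arange(start_year, start_year + n_years)
    days = model.intercept + model.slope * years.astype(float)
    if stochastic:
        if rng is None:
            rng = np.random.default_rng(seed)
        days = days + rng.normal(0.0, model.residual_sd, size=n_years)
    return pd.DataFrame({"year": years, "day": days})


@dataclass(frozen=True)
class GradualSiteParams:
    """Site-specific parameterization of the gradual-change model.

    ``w0_quad = (c0, c1, c2)`` gives baseline fitness W0(d) = c0 + c1 d +
    c2 d^2 (floored at 0); ``s_line = (a0, a1)`` the raw selection
    differential S(d) = a0 + a1 d; ``bv_line = (e0, e1)`` the fitness slope
    b(d) = e0 + e1 d, which is divided by W0(d) at use and evaluated at the
    site-referenced day d + ``b_day_offset``.  ``min_displacement`` is an
    optional floor (cm^2/g) on the total downward trait displacement,
    corresponding to a minimum attainable SLA; off by default.
    """

    site: str
    w0_quad: Tuple[float, float, float]
    s_line: Tuple[float, float]
    bv_line: Tuple[float, float]
    b_day_offset: float = 0.0
    h2: float = 0.10
    generation_years: int = 5
    plasticity_slope: float = 1.323
    start_year: int = 2023
    n0: float = 200.0
    extinction_threshold: float = 2.0
    end_year: int = 2400
    min_displacement: Optional[float] = None

    def __post_init__(self) -> None:
        if self.generation_years < 1:
            raise ValueError("generation_years must be >= 1")
        if not math.isfinite(self.plasticity_slope):
            raise ValueError("plasticity_slope must be finite")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year")

    def baseline_fitness(self, d: float) -> float:
        """W0(d): baseline mean absolute fitness, floored at zero."""
        c0, c1, c2 = self.w0_quad
        return max(0.0, c0 + c1 * d + c2 * d * d)

    def selection(self, d: float) -> float:
        """S(d): raw selection differential (cm^2/g) at station day d."""
        a0, a1 = self.s_line
        return a0 + a1 * d

    def fitness_slope(self, d: float) -> float:
        """b evaluated at the site-referenced day d + b_day_offset."""
        e0, e1 = self.bv_line
        ds = d + self.b_day_offset
        return e0 + e1 * ds


def hybrid_params(**overrides) -> GradualSiteParams:
    """Hybrid-zone population parameterization (below replacement today)."""
    defaults = dict(
        site="hybrid",
        w0_quad=(1.352, -0.0202, 0.000126),
        s_line=(-10.041, 0.040),
        bv_line=(-0.0224, 0.00012),
        b_day_offset=17.0,
    )
    defaults.update(overrides)
    return GradualSiteParams(**defaults)


def aggregata_params(**overrides) -> GradualSiteParams:
    """*Ipomopsis aggregata* population parameterization (above replacement)."""
    defaults = dict(
        site="aggregata",
        w0_quad=(7.504, -0.1378, 0.00067),
        s_line=(31.493, -0.252),
        bv_line=(0.0144, -0.00012),
        b_day_offset=6.0,
    )
    defaults.update(overrides)
    return GradualSiteParams(**defaults)


def selection_at_day(params: GradualSiteParams, d: float) -> float:
    """Raw selection differential S(d) in cm^2/g."""
    return params.selection(d)


def baseline_fitness_at_day(params: GradualSiteParams, d: float) -> float:
    """Baseline mean absolute fitness W0(d), floored at zero."""
    return params.baseline_fitness(d)


def plastic_shift(delta_d: float, slope: float = 1.323) -> float:
    """Plastic SLA shift (cm^2/g) for a snowmelt-day difference in days."""
    return slope * delta_d


def run_gradual_model(
    params: GradualSiteParams,
    evolution: bool = True,
    plasticity: bool = False,
    env_stochastic: bool = False,
    demo_stochastic: bool = False,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    snowmelt: Optional[SnowmeltModel] = None,
) -> Trajectory:
    """Run one yearly trajectory of the gradual environmental change model.

    The yearly loop runs from ``start_year`` to ``end_year`` (or functional
    extinction).  Each year the snowmelt day is computed (or drawn), the
    genetic trait change is incremented by h2*S(d)/5 when ``evolution`` is
    on, and the plastic displacement tracks the accumulated snowmelt
    difference from the first year when ``plasticity`` is on.  Every
    ``generation_years`` years one population update is applied at that
    year's snowmelt day.  Rows are recorded every year; ``w_mean`` is NaN in
    years without a generation turnover.

    With both stochasticity flags off the run is deterministic and
    independent of ``seed``.
    """
    snow = snowmelt or SnowmeltModel()
    if rng is None:
        rng = np.random.default_rng(seed)
    n_years = params.end_year - params.start_year + 1
    series = snowmelt_series(
        snow, params.start_year, n_years, stochastic=env_stochastic, rng=rng
    )
    days = series["day"].to_numpy()

    rows = []
    dz = 0.0
    n = float(params.n0)
    d_first: Optional[float] = None
    gy = params.generation_years
    extinct = False
    for i, year in enumerate(range(params.start_year, params.end_year + 1)):
        d = float(days[i])
        if d_first is None:
            d_first = d
        if evolution:
            dz += params.h2 * params.selection(d) / gy
        shift = params.plasticity_slope * (d - d_first) if plasticity else 0.0
        disp = dz + shift
        if params.min_displacement is not None:
            disp = max(disp, params.min_displacement)
        generation = (year - params.start_year) // gy
        is_update_year = (year - params.start_year) % gy == 0
        if is_update_year:
            if n < params.extinction_threshold:
                rows.append((year, generation, d, dz, shift, np.nan, n, True))
                extinct = True
                break
            w0 = params.baseline_fitness(d)
            if w0 > 0:
                w = w0 * max(0.0, 1.0 + (params.fitness_slope(d) / w0) * disp)
            else:
                w = 0.0
            rows.append((year, generation, d, dz, shift, w, n, True))
            lam = n * w
            if demo_stochastic:
                n = float(rng.poisson(lam)) if lam < 1e8 else float(round(lam))
            else:
                n = lam
        else:
            rows.append((year, generation, d, dz, shift, np.nan, n, False))
    data = pd.DataFrame(
        rows,
        columns=[
            "year",
            "generation",
            "snowmelt_day",
            "delta_z",
            "plastic_shift",
            "w_mean",
            "n",
            "is_generation",
        ],
    )
    # total displacement actually applied to fitness
    data["displacement"] = data["delta_z"] + data["plastic_shift"]
    if params.min_displacement is not None:
        data["displacement"] = data["displacement"].clip(lower=params.min_displacement)
    return Trajectory(
        data,
        params.extinction_threshold,
        params={
            "model": "gradual",
            "site": params.site,
            "evolution": evolution,
            "plasticity": plasticity,
            "env_stochastic": env_stochastic,
            "demo_stochastic": demo_stochastic,
            "extinct": extinct,
        },
    )


@dataclass(frozen=True)
class RescueProbability:
    """Rescued fraction over replicates with a Wilson confidence interval."""

    fraction: float
    ci_low: float
    ci_high: float
    n_rescued: int
    n_reps: int


def rescue_probability(
    params: GradualSiteParams,
    evolution: bool = True,
    plasticity: bool = True,
    env_stochastic: bool = True,
    demo_stochastic: bool = True,
    n_reps: int = 200,
    seed: Optional[int] = None,
    snowmelt: Optional[SnowmeltModel] = None,
) -> RescueProbability:
    """Fraction of replicates escaping functional extinction by ``end_year``.

    A replicate is rescued iff its population never fell below the
    extinction threshold through the horizon.  Replicates use independent
    generators spawned from the root seed.  With all stochasticity off the
    fraction is degenerate (exactly 0 or 1).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    any_random = env_stochastic or demo_stochastic
    if any_random and seed is None:
        raise ValueError("stochastic replicates require a seed")
    if not any_random:
        n_reps = 1
    children = np.random.SeedSequence(seed).spawn(n_reps) if any_random else [None]
    rescued = 0
    for child in children:
        rng = np.random.default_rng(child)
        traj = run_gradual_model(
            params,
            evolution=evolution,
            plasticity=plasticity,
            env_stochastic=env_stochastic,
            demo_stochastic=demo_stochastic,
            rng=rng,
            snowmelt=snowmelt,
        )
        if traj.extinction_step() is None:
            rescued += 1
    frac = rescued / n_reps
    lo, hi = proportion_confint(rescued, n_reps, alpha=0.05, method="wilson")
    return RescueProbability(frac, float(lo), float(hi), rescued, n_reps)
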