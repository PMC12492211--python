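"""Phenotypic selection inference from plant-level trait/fitness tables.

The data are field panels of individual plants: site, calendar year, trait
value (SLA, cm^2/g) and a binary fitness component (survival to flowering).
Directional selection is summarized by the selection differential — the
covariance of relative fitness with the trait — estimated as the
least-squares coefficient of the trait in a linear model of relative
fitness, optionally with site indicator variables.  With the trait
standardized to unit SD the coefficient is the SD-standardized differential
S'.  Curvature is summarized by the quadratic selection gradient, twice the
coefficient of the squared standardized trait.  Because the fitness
component is binary, significance is assessed with a binomial-family
logit-link GLM on the same design, while the reported effect sizes stay on
the least-squares scale.

The environmental sensitivity of selection is the ordinary least-squares
line of the yearly differential (or yearly b/v) on that year's snowmelt
day.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TRAIT_COLUMN",
    "SelectionEstimate",
    "SensitivityFit",
    "standardize_trait",
    "relative_fitness",
    "mean_trait_table",
    "estimate_selection_differential",
    "estimate_quadratic_gradient",
    "test_selection_glm",
    "yearly_selection_differentials",
    "b_over_v_by_year",
    "fit_environmental_sensitivity",
]

logger = logging.getLogger(__name__)

TRAIT_COLUMN = "sla_cm2_per_g"
FITNESS_COLUMN = "survival"


@dataclass(frozen=True)
class SelectionEstimate:
    """A directional differential or quadratic gradient with its scale.

    ``estimate`` is dimensionless for ``scale='standardized'`` (the trait had
    sample SD 1 before fitting) and in trait units (cm^2/g) for
    ``scale='raw'``: the covariance of relative fitness with the raw trait,
    so raw = standardized x sample trait SD.
    ``p_value`` is the two-sided Wald probability from the binomial GLM on
    the same design (None when the GLM was not requested, NaN under perfect
    separation).
    """

    kind: str  # "directional_differential" | "quadratic_gradient"
    scale: str  # "standardized" | "raw"
    scope: str  # "overall_mean_trait" | "within_year"
    estimate: float
    se: float
    p_value: Optional[float]
    n: int
    year: Optional[int] = None


@dataclass(frozen=True)
class SensitivityFit:
    """OLS line of a yearly selection summary on snowmelt day."""

    intercept: float
    slope: float
    response: str  # "raw_differential" | "standardized_differential" | "b_over_v"
    r: float
    n_years: int
    slope_se: float = float("nan")


def _check_columns(table: pd.DataFrame, columns: Sequence[str]) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")


def standardize_trait(
    table: pd.DataFrame,
    scope: str = "global",
    trait_col: str = TRAIT_COLUMN,
) -> pd.DataFrame:
    """Add a ``trait_std`` column with mean 0 and sample SD 1 (n-1 denominator).

    ``scope='global'`` standardizes across all plants; ``scope='within_year'``
    standardizes separately within each calendar year.  A group with fewer
    than two distinct trait values cannot be standardized and raises a
    ``ValueError`` naming the group.
    """
    _check_columns(table, [trait_col] + (["year"] if scope == "within_year" else []))
    if scope not in ("global", "within_year"):
        raise ValueError(f"unknown scope: {scope!r}")
    out = table.copy()

    def zscore(values: pd.Series, label: str) -> pd.Series:
        sd = values.std(ddof=1)
        if not np.isfinite(sd) or sd == 0.0:
            raise ValueError(f"zero variance in trait for group {label!r}")
        return (values - values.mean()) / sd

    if scope == "global":
        out["trait_std"] = zscore(out[trait_col], "global")
    else:
        out["trait_std"] = out.groupby("year", group_keys=False)[trait_col].apply(
            lambda s: zscore(s, str(s.name))
        )
    return out


def relative_fitness(
    table: pd.DataFrame, fitness_col: str = FITNESS_COLUMN
) -> pd.DataFrame:
    """Add a ``relative_fitness`` column: fitness divided by its mean.

    The relativized column has mean exactly 1.  All-zero fitness raises.
    """
    _check_columns(table, [fitness_col])
    mean = table[fitness_col].mean()
    if not mean > 0:
        raise ValueError("mean fitness is zero; cannot relativize")
    out = table.copy()
    out["relative_fitness"] = out[fitness_col] / mean
    return out


def mean_trait_table(table: pd.DataFrame, trait_col: str = TRAIT_COLUMN) -> pd.DataFrame:
    """Collapse repeated yearly measurements to one row per plant.

    The trait is averaged over a plant's measurement years; site and the
    (plant-level) survival outcome are carried through.  Records with
    missing trait or fitness are dropped listwise with a logged count.
    """
    _check_columns(table, ["plant_id", "site", trait_col, FITNESS_COLUMN])
    n0 = len(table)
    clean = table.dropna(subset=[trait_col, FITNESS_COLUMN])
    if len(clean) < n0:
        logger.info("dropped %d records with missing trait/fitness", n0 - len(clean))
    grouped = clean.groupby("plant_id", sort=False).agg(
        site=("site", "first"),
        **{trait_col: (trait_col, "mean")},
        survival=(FITNESS_COLUMN, "max"),
    )
    return grouped.reset_index()


def _design(
    table: pd.DataFrame,
    predictor_cols: Sequence[str],
    covariate_site: bool,
) -> Tuple[np.ndarray, Sequence[str]]:
    """Intercept + predictors + (optionally) site indicator columns."""
    parts = [np.ones(len(table))]
    names = ["const"]
    for col in predictor_cols:
        parts.append(table[col].to_numpy(dtype=float))
        names.append(col)
    if covariate_site:
        sites = sorted(table["site"].unique())
        if len(sites) < 2:
            raise ValueError("site covariate requested but table has a single site")
        counts = table["site"].value_counts()
        thin = [s for s in sites if counts[s] < 2]
        if thin:
            raise ValueError(f"sites with fewer than 2 records: {thin}")
        for s in sites[1:]:  # first site is the reference level
            parts.append((table["site"] == s).to_numpy(dtype=float))
            names.append(f"site[{s}]")
    X = np.column_stack(parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design matrix (check sites and predictors)")
    return X, names


def _glm_pvalues(
    y: np.ndarray, X: np.ndarray, names: Sequence[str]
) -> Dict[str, float]:
    """Two-sided Wald p-values from a binomial logit GLM fitted by IRLS.

    Perfect separation is flagged with a warning and yields NaN p-values
    rather than a spuriously tiny probability.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("no variation in the binary response")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        except Exception as exc:  # IRLS blow-up under separation
            warnings.warn(f"binomial GLM failed ({exc}); p-values set to NaN")
            return {name: float("nan") for name in names}
        separated = any("separation" in str(w.message).lower() for w in caught)
    pvals = np.asarray(fit.pvalues, dtype=float)
    if separated or not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 30):
        warnings.warn("perfect separation detected; GLM p-values set to NaN")
        pvals = np.full_like(pvals, np.nan)
    return dict(zip(names, pvals))


def estimate_selection_differential(
    table: pd.DataFrame,
    scale: str = "standardized",
    scope: str = "overall_mean_trait",
    covariate_site: bool = True,
    glm_pvalue: bool = True,
    year: Optional[int] = None,
    trait_col: str = TRAIT_COLUMN,
) -> SelectionEstimate:
    """Directional selection differential from a prepared table.

    The table must already carry ``relative_fitness`` and, for
    ``scale='standardized'``, a ``trait_std`` column (see
    :func:`relative_fitness` and :func:`standardize_trait`).  The estimate is
    the least-squares coefficient of the trait in a linear model of relative
    fitness on trait (+ site indicators when ``covariate_site``).  Without a
    site covariate the standardized estimate equals the sample covariance of
    relative fitness with the standardized trait.  The p-value comes from
    the binomial GLM on the same design.
    """
    if scale not in ("standardized", "raw"):
        raise ValueError(f"unknown scale: {scale!r}")
    predictor = "trait_std" if scale == "standardized" else trait_col
    _check_columns(table, [predictor, "relative_fitness"])
    X, names = _design(table, [predictor], covariate_site)
    w = table["relative_fitness"].to_numpy(dtype=float)
    ols = sm.OLS(w, X).fit()
    idx = names.index(predictor)
    # the differential is a covariance, so the raw-scale estimate carries
    # trait units (cm^2/g): slope per unit trait times the trait variance;
    # standardized scale needs no factor because the predictor has SD 1
    unit = table[trait_col].var(ddof=1) if scale == "raw" else 1.0
    p_value: Optional[float] = None
    if glm_pvalue:
        p_value = _glm_pvalues(
            table[FITNESS_COLUMN].to_numpy(dtype=float), X, names
        )[predictor]
    return SelectionEstimate(
        kind="directional_differential",
        scale=scale,
        scope=scope,
        estimate=float(ols.params[idx] * unit),
        se=float(ols.bse[idx] * unit),
        p_value=p_value,
        n=len(table),
        year=year,
    )


def estimate_quadratic_gradient(
    table: pd.DataFrame,
    scope: str = "within_year",
    covariate_site: bool = True,
    glm_pvalue: bool = True,
    year: Optional[int] = None,
) -> SelectionEstimate:
    """Quadratic selection gradient: 2x the squared-trait OLS coefficient.

    Fits relative fitness on the standardized trait, its square and site
    indicators; negative gradients indicate curvature consistent with
    stabilizing selection.  Requires at least four distinct trait values.
    """
    _check_columns(table, ["trait_std", "relative_fitness"])
    if table["trait_std"].nunique() < 4:
        raise ValueError("need at least 4 distinct trait values for a quadratic fit")
    work = table.copy()
    work["trait_std_sq"] = work["trait_std"] ** 2
    X, names = _design(work, ["trait_std", "trait_std_sq"], covariate_site)
    w = work["relative_fitness"].to_numpy(dtype=float)
    ols = sm.OLS(w, X).fit()
    idx = names.index("trait_std_sq")
    p_value: Optional[float] = None
    if glm_pvalue:
        p_value = _glm_pvalues(
            work[FITNESS_COLUMN].to_numpy(dtype=float), X, names
        )["trait_std_sq"]
    return SelectionEstimate(
        kind="quadratic_gradient",
        scale="standardized",
        scope=scope,
        estimate=2.0 * float(ols.params[idx]),
        se=2.0 * float(ols.bse[idx]),
        p_value=p_value,
        n=len(work),
        year=year,
    )


def test_selection_glm(
    table: pd.DataFrame,
    terms: Sequence[str] = ("trait_std",),
    covariate_site: bool = True,
) -> Dict[str, float]:
    """Wald p-values per term from the binomial logit GLM.

    Uses the same design matrix as the least-squares effect estimates; the
    response is the raw binary fitness component.
    """
    _check_columns(table, list(terms) + [FITNESS_COLUMN])
    X, names = _design(table, list(terms), covariate_site)
    pvals = _glm_pvalues(table[FITNESS_COLUMN].to_numpy(dtype=float), X, names)
    return {t: pvals[t] for t in terms}


def yearly_selection_differentials(
    table: pd.DataFrame,
    scale: str = "standardized",
    covariate_site: bool = True,
    glm_pvalue: bool = False,
    trait_col: str = TRAIT_COLUMN,
) -> pd.DataFrame:
    """Per-year differentials: standardize and relativize within each year.

    Each year is analyzed alone (its own standardization and mean fitness),
    pooling sites with a site factor when ``covariate_site``.  Returns one
    row per year with estimate, SE, p (optional) and n.
    """
    _check_columns(table, ["year", "site", trait_col, FITNESS_COLUMN])
    rows = []
    for yr, sub in table.groupby("year"):
        sub = standardize_trait(sub, scope="global", trait_col=trait_col)
        sub = relative_fitness(sub)
        est = estimate_selection_differential(
            sub,
            scale=scale,
            scope="within_year",
            covariate_site=covariate_site,
            glm_pvalue=glm_pvalue,
            year=int(yr),
            trait_col=trait_col,
        )
        rows.append(
            {
                "year": int(yr),
                "estimate": est.estimate,
                "se": est.se,
                "p_value": est.p_value,
                "n": est.n,
            }
        )
    return pd.DataFrame(rows)


def b_over_v_by_year(
    table: pd.DataFrame, trait_col: str = TRAIT_COLUMN
) -> pd.DataFrame:
    """Yearly b/v: OLS slope of absolute survival on the raw trait over mean survival."""
    _check_columns(table, ["year", trait_col, FITNESS_COLUMN])
    rows = []
    for yr, sub in table.groupby("year"):
        x = sub[trait_col].to_numpy(dtype=float)
        y = sub[FITNESS_COLUMN].to_numpy(dtype=float)
        v = y.mean()
        if v == 0:
            raise ValueError(f"mean survival is zero in year {yr}")
        slope = np.polyfit(x, y, 1)[0]
        rows.append({"year": int(yr), "b": float(slope), "v": float(v), "b_over_v": float(slope / v)})
    return pd.DataFrame(rows)


def fit_environmental_sensitivity(
    yearly: Sequence[Tuple[int, float]],
    snowmelt: Sequence[Tuple[int, float]],
    response: str = "raw_differential",
) -> SensitivityFit:
    """OLS line of a yearly selection summary on snowmelt day.

    ``yearly`` is (year, estimate) pairs; ``snowmelt`` is (year, day) pairs.
    Years must match one-to-one; unmatched years raise an error listing
    them.  Returns intercept, slope (response units per day) and Pearson r.
    """
    est = dict(yearly)
    days = dict(snowmelt)
    unmatched = sorted(set(est) ^ set(days))
    if unmatched:
        raise ValueError(f"years without a matching pair: {unmatched}")
    years = sorted(est)
    if len(years) < 2:
        raise ValueError("need at least 2 matched years")
    x = np.array([days[y] for y in years], dtype=float)
    y = np.array([est[y] for y in years], dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    ols = sm.OLS(y, X).fit()
    if np.std(y) == 0 or np.std(x) == 0:
        r = 0.0
    else:
        r = float(stats.pearsonr(x, y)[0])
    return SensitivityFit(
        intercept=float(ols.params[0]),
        slope=float(ols.params[1]),
        response=response,
        r=r,
        n_years=len(years),
        slope_se=float(ols.bse[1]),
    )
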