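"""Selection-differential and gradient estimation against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from evorescue import (
    SyntheticTruth,
    estimate_quadratic_gradient,
    estimate_selection_differential,
    fit_environmental_sensitivity,
    generate_trait_fitness,
    relative_fitness,
    standardize_trait,
)
from evorescue import test_selection_glm as glm_pvalues
from evorescue.selection import TRAIT_COLUMN

from conftest import random_table


class TestStandardize:
    def test_global_matches_hand_zscores(self, four_plant_table):
        out = standardize_trait(four_plant_table)
        # hand z-scores of (1,2,3,4) with sample SD 1.29099
        expected = [-1.161895, -0.387298, 0.387298, 1.161895]
        assert out["trait_std"].to_numpy() == pytest.approx(expected, abs=1e-6)
        assert out["trait_std"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["trait_std"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_within_year_each_group_unit_sd(self):
        rng = np.random.default_rng(0)
        tbl = pd.concat(
            [
                random_table(rng, 30).assign(year=2010, **{TRAIT_COLUMN: rng.normal(200, 10, 30)}),
                random_table(rng, 30).assign(year=2011, **{TRAIT_COLUMN: rng.normal(300, 40, 30)}),
            ],
            ignore_index=True,
        )
        out = standardize_trait(tbl, scope="within_year")
        for _, grp in out.groupby("year"):
            assert grp["trait_std"].mean() == pytest.approx(0.0, abs=1e-10)
            assert grp["trait_std"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_zero_variance_names_group(self, four_plant_table):
        flat = four_plant_table.assign(**{TRAIT_COLUMN: 5.0})
        with pytest.raises(ValueError, match="zero variance.*global"):
            standardize_trait(flat)


class TestRelativeFitness:
    @pytest.mark.parametrize(
        "survival, expected",
        [
            ([1, 1, 0, 0], [2.0, 2.0, 0.0, 0.0]),
            ([1, 1, 1, 1], [1.0, 1.0, 1.0, 1.0]),
            ([1, 0, 0, 0], [4.0, 0.0, 0.0, 0.0]),
        ],
    )
    def test_division_by_mean(self, four_plant_table, survival, expected):
        out = relative_fitness(four_plant_table.assign(survival=survival))
        assert out["relative_fitness"].tolist() == expected
        assert out["relative_fitness"].mean() == pytest.approx(1.0, abs=1e-15)

    def test_all_dead_errors(self, four_plant_table):
        with pytest.raises(ValueError, match="mean fitness"):
            relative_fitness(four_plant_table.assign(survival=0))


class TestDifferential:
    def test_hand_example(self, prepared_four):
        est = estimate_selection_differential(
            prepared_four, covariate_site=False, glm_pvalue=False
        )
        assert est.estimate == pytest.approx(-1.0328, abs=1e-4)

    def test_equals_covariance_oracle(self):
        # no site covariate + standardized scale == sample covariance of
        # relative fitness with the standardized trait
        for seed in range(10):
            rng = np.random.default_rng(seed)
            tbl = relative_fitness(standardize_trait(random_table(rng, 40)))
            est = estimate_selection_differential(
                tbl, covariate_site=False, glm_pvalue=False
            )
            oracle = np.cov(tbl["relative_fitness"], tbl["trait_std"], ddof=1)[0, 1]
            assert abs(est.estimate - oracle) < 1e-10

    def test_constant_fitness_gives_zero(self, four_plant_table):
        tbl = relative_fitness(standardize_trait(four_plant_table.assign(survival=1)))
        est = estimate_selection_differential(tbl, covariate_site=False, glm_pvalue=False)
        assert est.estimate == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        scale=st.floats(0.01, 100.0),
        shift=st.floats(-500.0, 500.0),
        seed=st.integers(0, 100),
    )
    def test_affine_invariance(self, scale, shift, seed):
        # standardized estimate is unchanged by affine rescaling of the trait
        rng = np.random.default_rng(seed)
        tbl = random_table(rng, 30)
        rescaled = tbl.assign(**{TRAIT_COLUMN: tbl[TRAIT_COLUMN] * scale + shift})

        def sprime(t):
            prep = relative_fitness(standardize_trait(t))
            return estimate_selection_differential(
                prep, covariate_site=False, glm_pvalue=False
            ).estimate

        assert abs(sprime(tbl) - sprime(rescaled)) < 1e-10

    def test_raw_equals_standardized_times_sd(self):
        rng = np.random.default_rng(3)
        tbl = relative_fitness(standardize_trait(random_table(rng, 60)))
        std = estimate_selection_differential(tbl, covariate_site=False, glm_pvalue=False)
        raw = estimate_selection_differential(
            tbl, scale="raw", covariate_site=False, glm_pvalue=False
        )
        sd = tbl[TRAIT_COLUMN].std(ddof=1)
        # the raw differential carries trait units: S = S' x SD
        assert raw.estimate == pytest.approx(std.estimate * sd, abs=1e-8)
        # and equals the covariance with the raw trait (no-covariate case)
        oracle = np.cov(tbl["relative_fitness"], tbl[TRAIT_COLUMN], ddof=1)[0, 1]
        assert raw.estimate == pytest.approx(oracle, abs=1e-8)

    def test_site_covariate_removes_confounding(self):
        # sites differ in both mean trait and mean survival; within each
        # site the trait is fitness-independent, so the true differential
        # with the site held fixed is zero
        rng = np.random.default_rng(8)
        tbl = pd.DataFrame(
            {
                "plant_id": [f"p{i}" for i in range(20)],
                "site": ["agg"] * 10 + ["hyb"] * 10,
                "year": 2010,
                TRAIT_COLUMN: np.r_[rng.normal(220, 5, 10), rng.normal(280, 5, 10)],
                "survival": [1] * 10 + [0] * 10,
            }
        )
        prep = relative_fitness(standardize_trait(tbl))
        with_site = estimate_selection_differential(prep, glm_pvalue=False)
        without = estimate_selection_differential(
            prep, covariate_site=False, glm_pvalue=False
        )
        assert with_site.estimate == pytest.approx(0.0, abs=1e-8)
        assert abs(without.estimate) > 0.5

    def test_collinear_design_errors(self):
        tbl = pd.DataFrame(
            {
                "plant_id": ["a", "b"],
                "site": ["x", "y"],
                "year": 2010,
                TRAIT_COLUMN: [1.0, 2.0],
                "survival": [1, 0],
            }
        )
        prep = relative_fitness(standardize_trait(tbl))
        with pytest.raises(ValueError):
            estimate_selection_differential(prep, glm_pvalue=False)


class TestQuadraticGradient:
    @staticmethod
    def _table(z, w):
        return pd.DataFrame(
            {
                "trait_std": z,
                "relative_fitness": w,
                "survival": (np.asarray(w) > np.median(w)).astype(int),
            }
        )

    def test_linear_surface_zero_curvature(self):
        z = np.linspace(-1.5, 1.5, 13)
        est = estimate_quadratic_gradient(
            self._table(z, 1.0 + 0.4 * z), covariate_site=False, glm_pvalue=False
        )
        assert est.estimate == pytest.approx(0.0, abs=1e-10)

    def test_concave_surface_exact_gradient(self):
        # w = 1 - z^2 has quadratic OLS coefficient -1, gradient 2*(-1) = -2
        z = np.linspace(-1.5, 1.5, 13)
        est = estimate_quadratic_gradient(
            self._table(z, 1.0 - z**2), covariate_site=False, glm_pvalue=False
        )
        assert est.estimate == pytest.approx(-2.0, abs=1e-10)

    def test_convex_surface_positive(self):
        z = np.linspace(-1.5, 1.5, 13)
        est = estimate_quadratic_gradient(
            self._table(z, z**2), covariate_site=False, glm_pvalue=False
        )
        assert est.estimate > 0

    def test_too_few_distinct_traits(self):
        est_tbl = self._table([-1.0, 0.0, 1.0, -1.0], [1, 1, 1, 1])
        with pytest.raises(ValueError, match="4 distinct"):
            estimate_quadratic_gradient(est_tbl, covariate_site=False, glm_pvalue=False)


class TestBinomialGLM:
    def test_type_one_error_rate_near_nominal(self):
        # under the null (trait unrelated to survival) the Wald test should
        # reject at roughly its nominal 5% level
        rejections = 0
        n_tables = 400
        rng = np.random.default_rng(11)
        truth = SyntheticTruth(n_plants=100, beta=0.0)
        for _ in range(n_tables):
            tbl = standardize_trait(generate_trait_fitness(truth, rng=rng))
            p = glm_pvalues(tbl)["trait_std"]
            rejections += p < 0.05
        rate = rejections / n_tables
        assert 0.03 <= rate <= 0.08

    def test_power_against_strong_selection(self):
        # a strong monotone effect at n=200 is essentially always detected
        hits = 0
        n_tables = 100
        rng = np.random.default_rng(12)
        truth = SyntheticTruth(n_plants=200, beta=-3.0)
        for _ in range(n_tables):
            tbl = standardize_trait(generate_trait_fitness(truth, rng=rng))
            p = glm_pvalues(tbl)["trait_std"]
            hits += (p == p) and p < 0.001  # NaN-safe
        assert hits >= 95

    def test_no_response_variation_errors(self, prepared_four):
        with pytest.raises(ValueError, match="no variation"):
            glm_pvalues(prepared_four.assign(survival=1), covariate_site=False)

    def test_perfect_separation_warns_and_nans(self):
        z = np.linspace(-2, 2, 40)
        tbl = pd.DataFrame(
            {"trait_std": z, "survival": (z > 0).astype(int)}
        )
        with pytest.warns(UserWarning, match="separation|GLM failed"):
            p = glm_pvalues(tbl, covariate_site=False)["trait_std"]
        assert np.isnan(p)


class TestEnvironmentalSensitivity:
    def test_two_point_exact_line(self):
        fit = fit_environmental_sensitivity(
            [(2010, -6.0), (2011, -4.0)], [(2010, 100.0), (2011, 150.0)]
        )
        assert fit.slope == pytest.approx(0.04, abs=1e-12)
        assert fit.intercept == pytest.approx(-10.0, abs=1e-10)

    def test_constant_response_zero_slope(self):
        years = [(y, -5.0) for y in range(2009, 2021)]
        days = [(y, 100.0 + 3 * (y - 2009)) for y in range(2009, 2021)]
        fit = fit_environmental_sensitivity(years, days)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r == 0.0

    def test_unmatched_years_listed(self):
        with pytest.raises(ValueError, match="2012"):
            fit_environmental_sensitivity(
                [(2010, -6.0), (2012, -4.0)], [(2010, 100.0), (2011, 150.0)]
            )

    def test_recovers_known_line_from_noisy_years(self):
        # yearly differentials generated from the known sensitivity line
        # S = -10.041 + 0.040 d with SD-0.5 noise over 12 years
        rng = np.random.default_rng(21)
        days = rng.uniform(110, 160, 12)
        years = list(range(2009, 2021))
        s = -10.041 + 0.040 * days + rng.normal(0, 0.5, 12)
        fit = fit_environmental_sensitivity(
            list(zip(years, s)), list(zip(years, days))
        )
        assert abs(fit.slope - 0.040) <= 2 * fit.slope_se


class TestParameterRecovery:
    def test_sprime_recovery_and_calibration(self):
        # 500 synthetic tables at the study's strongest selection: the mean
        # estimate tracks the realized in-table truth within 0.02 and the
        # 2-SE interval covers the truth at least 93% of the time
        rng = np.random.default_rng(31)
        truth = SyntheticTruth(n_plants=400)
        errors, covered = [], 0
        n_tables = 500
        for _ in range(n_tables):
            tbl = generate_trait_fitness(truth, rng=rng)
            prep = relative_fitness(standardize_trait(tbl))
            est = estimate_selection_differential(
                prep, covariate_site=False, glm_pvalue=False
            )
            errors.append(est.estimate - tbl.attrs["true_sprime"])
            covered += abs(est.estimate - tbl.attrs["true_sprime"]) <= 2 * est.se
        assert abs(np.mean(errors)) < 0.02
        assert covered / n_tables >= 0.93
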