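"""Individual differences: normalization, factors, correlations, RT gradients."""

import numpy as np
import pandas as pd
import pytest

from hierdcm.behavior import (
    ability_regression,
    correlate_factors,
    first_eigenvariate_factor,
    partial_correlation,
    rt_gradient_analysis,
    zscore_within_subject,
)
from hierdcm.cohort import CohortConfig, generate_cohort


class TestZscore:
    def test_reference_values(self):
        z = zscore_within_subject(np.arange(1, 9, dtype=float)[None, :])
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)
        assert z.max() == pytest.approx(1.4289, abs=1e-4)

    def test_between_subject_offsets_removed(self, rng):
        base = rng.normal(size=(1, 6))
        values = np.vstack([base + 10, base - 3])
        z = zscore_within_subject(values)
        assert np.allclose(z[0], z[1])

    def test_single_condition_error(self):
        with pytest.raises(ValueError):
            zscore_within_subject(np.ones((3, 1)))

    def test_zero_variance_names_subject(self):
        vals = np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        with pytest.raises(ValueError, match="1"):
            zscore_within_subject(vals)


class TestEigenvariate:
    def test_single_variable_equals_zscores(self, rng):
        x = rng.normal(2.0, 3.0, size=30)
        fac = first_eigenvariate_factor(x[:, None])
        z = (x - x.mean()) / x.std(ddof=1)
        assert np.allclose(fac.scores, z)

    def test_two_perfectly_correlated_variables(self, rng):
        x = rng.normal(size=40)
        fac = first_eigenvariate_factor(np.column_stack([x, 2.0 * x + 1.0]))
        assert np.allclose(np.abs(fac.loadings), np.abs(fac.loadings[0]))
        z = (x - x.mean()) / x.std(ddof=1)
        assert abs(np.corrcoef(fac.scores, z)[0, 1]) == pytest.approx(1.0)

    def test_sign_convention_positive(self, rng):
        x = rng.normal(size=(50, 3))
        x[:, 0] = x[:, 1] * 0.9 + 0.1 * x[:, 0]
        fac = first_eigenvariate_factor(x)
        fac_neg = first_eigenvariate_factor(-x)
        assert fac.loadings.sum() > 0
        assert fac_neg.loadings.sum() > 0

    def test_variable_order_invariance_up_to_identity(self, rng):
        X = rng.normal(size=(40, 4)) + rng.normal(size=(40, 1))
        a = first_eigenvariate_factor(X)
        b = first_eigenvariate_factor(X[:, ::-1])
        assert np.allclose(a.scores, b.scores, atol=1e-10)

    def test_constant_column_dropped(self, rng):
        X = np.column_stack([rng.normal(size=20), np.full(20, 7.0)])
        with pytest.warns(RuntimeWarning):
            fac = first_eigenvariate_factor(X)
        assert fac.dropped == ["1"]

    def test_scores_zero_mean_unit_norm_loadings(self, rng):
        fac = first_eigenvariate_factor(rng.normal(size=(30, 5)))
        assert fac.scores.mean() == pytest.approx(0.0, abs=1e-10)
        assert np.linalg.norm(fac.loadings) == pytest.approx(1.0)


class TestCorrelateFactors:
    def test_identity(self):
        x = np.linspace(0, 1, 20)
        res = correlate_factors(x, x)
        assert res.r == pytest.approx(1.0)

    def test_planted_correlation_recovered(self, rng):
        n = 1000
        x = rng.standard_normal(n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        res = correlate_factors(x, y)
        assert res.r == pytest.approx(0.5, abs=0.06)

    def test_robust_regression_downweights_outlier(self, rng):
        import statsmodels.api as sm

        x = np.linspace(0, 1, 23)
        y = x.copy()
        x_full = np.append(x, 2.0)
        y_full = np.append(y, -10.0)
        res = correlate_factors(x_full, y_full)
        ols_slope = sm.OLS(y_full, sm.add_constant(x_full)).fit().params[1]
        assert abs(res.robust_slope - 1.0) < abs(ols_slope - 1.0)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            correlate_factors(np.ones(10), np.arange(10.0))


class TestPartialCorrelation:
    def test_no_controls_equals_pearson(self, rng):
        x, y = rng.standard_normal((2, 50))
        rho, _ = partial_correlation(x, y)
        assert rho == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_control_removes_shared_variance(self, rng):
        c = rng.standard_normal(60)
        rho, p = partial_correlation(c + 0.01 * rng.standard_normal(60), c, controls=c)
        assert abs(rho) < 0.2

    def test_matches_closed_form_for_gaussian_triple(self, rng):
        """Partial correlation of a known 3-variate Gaussian equals
        -P12 / sqrt(P11 P22) from the precision matrix P."""
        S = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.6], [0.3, 0.6, 1.0]])
        P = np.linalg.inv(S)
        expected = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
        X = rng.multivariate_normal(np.zeros(3), S, size=20_000)
        rho, _ = partial_correlation(X[:, 0], X[:, 1], controls=X[:, 2])
        assert rho == pytest.approx(expected, abs=0.02)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x, y, c = rng.standard_normal((3, 80))
        y = y + 0.5 * x + 0.3 * c
        rho, p = partial_correlation(x, y, controls=c)
        ref = pingouin.partial_corr(
            pd.DataFrame({"x": x, "y": y, "c": c}), x="x", y="y", covar="c"
        )
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_collinear_controls_error(self, rng):
        x, y = rng.standard_normal((2, 30))
        c = rng.standard_normal(30)
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(x, y, controls=np.column_stack([c, 2 * c]))

    def test_spearman_switch(self, rng):
        x, y = rng.standard_normal((2, 60))
        rho_p, _ = partial_correlation(x, y, method="pearson")
        rho_s, _ = partial_correlation(x, y, method="spearman")
        assert rho_p != rho_s


class TestRtGradient:
    def _cohort_inputs(self, seed):
        cohort = generate_cohort(CohortConfig(simulate_bold=False), seed=seed)
        return cohort.activations, cohort.rt_current.to_numpy(), cohort.rt_future.to_numpy()

    def test_constructed_identity_slopes(self, rng):
        n, k = 12, 8
        cur = rng.standard_normal((n, k))
        fut = rng.standard_normal((n, k))
        zcur = zscore_within_subject(cur)
        act = np.stack([zcur] * 3, axis=2)
        res = rt_gradient_analysis(act, cur, fut)
        cur_slopes = res.slopes.query("time == 'current'")["slope"]
        fut_slopes = res.slopes.query("time == 'future'")["slope"]
        assert np.allclose(cur_slopes, 1.0, atol=1e-10)
        assert abs(fut_slopes.mean()) < 0.2

    def test_planted_zone_pattern_recovered(self):
        """Caudal tracks current RT, rostral future RT, mid both — the sign
        pattern of the group-mean slopes recovers the plant in >= 90% of
        seeded cohorts, with a zone x time interaction."""
        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            act, cur, fut = self._cohort_inputs(seed)
            res = rt_gradient_analysis(act, cur, fut)
            g = res.slopes.groupby(["zone", "time"])["slope"].mean()
            ok = (
                g["caudal", "current"] > g["rostral", "current"]
                and g["rostral", "future"] > g["caudal", "future"]
                and g["mid", "current"] > 0
                and g["mid", "future"] > 0
            )
            hits += ok and res.interaction_p < 0.05
        assert hits >= int(0.9 * n_rep)

    def test_collinear_rts_flagged(self, rng):
        n, k = 10, 8
        cur = rng.standard_normal((n, k))
        act = np.stack([zscore_within_subject(cur)] * 3, axis=2)
        with pytest.warns(RuntimeWarning):
            res = rt_gradient_analysis(act, cur, cur.copy())
        assert res.collinear
        assert res.partials["rho"].isna().all()

    def test_missing_conditions_error(self, rng):
        act = rng.standard_normal((5, 8, 3))
        with pytest.raises(ValueError):
            rt_gradient_analysis(act, rng.standard_normal((5, 7)), rng.standard_normal((5, 8)))


class TestAbilityRegression:
    def test_exact_predictor(self, rng):
        td = rng.standard_normal(40)
        bu = rng.standard_normal(40)
        hi = rng.standard_normal(40)
        res = ability_regression(td, bu, hi, td)
        assert res.loc["topdown", "coef"] == pytest.approx(1.0, abs=1e-8)
        assert abs(res.loc["bottomup", "coef"]) < 1e-8

    def test_planted_two_predictor_model(self, rng):
        n = 200
        td, bu, hi = rng.standard_normal((3, n))
        ability = 0.5 * td + 0.5 * hi + 0.5 * rng.standard_normal(n)
        res = ability_regression(td, bu, hi, ability)
        assert res.loc["topdown", "p"] < 0.001
        assert res.loc["hierarchical", "p"] < 0.001
        assert res.loc["bottomup", "p"] > 0.05

    def test_duplicate_predictors_error(self, rng):
        x = rng.standard_normal(30)
        with pytest.raises(ValueError, match="collinear"):
            ability_regression(x, x, rng.standard_normal(30), rng.standard_normal(30))

    def test_low_ability_exclusion_runs(self, rng):
        td, bu, hi = rng.standard_normal((3, 30))
        ability = 0.5 * td + rng.standard_normal(30)
        ability[0] -= 6
        full = ability_regression(td, bu, hi, ability)
        trimmed = ability_regression(td, bu, hi, ability, exclude_low_ability=True)
        assert not np.allclose(full["coef"], trimmed["coef"])
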