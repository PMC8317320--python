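"""Standard errors, Wald/LRT tests and collinearity diagnostics."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from rmelm import (
    FitConfig,
    LongitudinalDesign,
    ModelState,
    coefficient_tests,
    collinearity_diagnostics,
    fisher_information,
    fit,
    lrt_global,
    sandwich_cov_beta,
)
from rmelm.inference import reference_df, wald_tests

from conftest import random_instance


def _fishers_at(design, state, lam):
    from dataclasses import replace

    pen = fisher_information(design, replace(state, lam=lam))
    unpen = fisher_information(design, replace(state, lam=0.0))
    return pen, unpen


class TestSandwichCovariance:
    def test_lam_zero_sandwich_equals_naive(self, rng):
        design, state = random_instance(rng, lam=0.0)
        pen, unpen = _fishers_at(design, state, 0.0)
        sw = sandwich_cov_beta(pen, unpen, mode="sandwich")
        naive = sandwich_cov_beta(pen, unpen, mode="naive")
        np.testing.assert_allclose(sw, naive, atol=1e-10)

    def test_variance_shrinks_monotonically_in_lambda(self, rng):
        design, state = random_instance(rng, n=8, sizes=np.full(8, 2), lam=0.0)
        prev = None
        for lam in (0.0, 1.0, 10.0, 100.0, 1e4):
            pen, unpen = _fishers_at(design, state, lam)
            d = np.diag(sandwich_cov_beta(pen, unpen))
            if prev is not None:
                assert np.all(d <= prev + 1e-12)
            prev = d
        assert np.all(prev < 1e-4)   # lam -> inf: covariance -> 0

    def test_two_subject_toy_equals_dense_triple_product(self, rng):
        design, state = random_instance(rng, n=2, p=2, q=1,
                                        sizes=np.array([2, 2]), lam=0.8)
        pen, unpen = _fishers_at(design, state, 0.8)
        p = design.p
        Fp = np.linalg.inv(pen.assemble())
        dense = (Fp @ unpen.assemble() @ Fp)[:p, :p]
        np.testing.assert_allclose(sandwich_cov_beta(pen, unpen), dense,
                                   atol=1e-10)


class TestWaldTests:
    def test_null_estimate_gives_p_one(self):
        t, p = wald_tests(np.array([0.0]), np.array([0.3]), df=57.0)
        assert t[0] == 0.0 and p[0] == pytest.approx(1.0)

    def test_borderline_call_at_ninety_percent_level(self):
        # estimate 0.09, SE 0.05: t = 1.8, two-sided p between .05 and .10
        t, p = wald_tests(np.array([0.09]), np.array([0.05]), df=294.0)
        assert t[0] == pytest.approx(1.8)
        assert 0.05 < p[0] < 0.10

    def test_matches_reference_t_distribution(self, rng):
        beta = rng.normal(size=20)
        se = rng.uniform(0.1, 2.0, 20)
        df = 37.0
        t, p = wald_tests(beta, se, df)
        np.testing.assert_allclose(p, 2 * stats.t.sf(np.abs(beta / se), df),
                                   rtol=1e-12)

    def test_zero_se_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_tests(np.array([1.0]), np.array([0.0]), 10.0)

    def test_df_modes(self):
        assert reference_df(100, 3, "t") == 97.0
        assert np.isinf(reference_df(100, 3, "normal"))

    def test_coefficient_tests_flag_rejections(self, rng):
        from rmelm import SimulationCell, simulate_dataset

        design, _ = simulate_dataset(SimulationCell(n=50, icc=0.2, rho=0.7, seed=5))
        res = fit(design, FitConfig(lambda_mode="zero"))
        rows = coefficient_tests(res, alpha=0.05)
        for row in rows:
            assert row.significant == (row.p_value < 0.05)
            assert row.odds_ratio == pytest.approx(np.exp(row.estimate))


class TestLRT:
    def test_identical_models_give_zero(self, rng):
        from rmelm import SimulationCell, simulate_dataset

        design, _ = simulate_dataset(SimulationCell(n=30, icc=0.2, rho=0.7, seed=2))
        res = fit(design, FitConfig(lambda_mode="zero"))
        stat, df, p = lrt_global(res, res)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_matches_pooled_glm_deviance_difference(self, rng):
        # random effects disabled via a frozen tiny Q: the joint criterion
        # reduces to the pooled logistic log-likelihood and the LRT must
        # agree with the reference GLM deviance test
        n = 80
        X = rng.standard_normal((n * 2, 3))
        subj = np.repeat(np.arange(n), 2)
        beta = np.array([0.8, -0.5, 0.0])
        y = (rng.random(n * 2) < 1 / (1 + np.exp(-X @ beta))).astype(float)
        design_full = LongitudinalDesign.from_arrays(subj, y, X)
        design_null = LongitudinalDesign.from_arrays(subj, y, X[:, :1])
        cfg = FitConfig(lambda_mode="zero", update_Q=False, Q_init=1e-10)
        full = fit(design_full, cfg)
        null = fit(design_null, cfg)
        stat, df, p = lrt_global(full, null)
        glm_full = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        glm_null = sm.GLM(y, X[:, :1], family=sm.families.Binomial()).fit()
        ref = glm_null.deviance - glm_full.deviance
        assert df == 2
        assert stat == pytest.approx(ref, abs=1e-3)
        assert p == pytest.approx(stats.chi2.sf(ref, 2), abs=1e-4)
        assert stat >= 0.0

    def test_mismatched_data_rejected(self, rng):
        from rmelm import SimulationCell, simulate_dataset

        d1, _ = simulate_dataset(SimulationCell(n=20, icc=0.2, rho=0.7, seed=1))
        d2, _ = simulate_dataset(SimulationCell(n=25, icc=0.2, rho=0.7, seed=1))
        r1 = fit(d1, FitConfig(lambda_mode="zero"))
        r2 = fit(d2, FitConfig(lambda_mode="zero"))
        with pytest.raises(ValueError, match="same data"):
            lrt_global(r1, r2)


class TestCollinearityDiagnostics:
    def test_orthonormal_columns_have_unit_condition_number(self):
        Q, _ = np.linalg.qr(np.random.default_rng(0).standard_normal((30, 4)))
        diag = collinearity_diagnostics(Q)
        assert diag.condition_number == pytest.approx(1.0, abs=1e-8)

    def test_duplicated_column_reports_infinite_condition(self, rng):
        x = rng.standard_normal(25)
        with pytest.warns(RuntimeWarning, match="collinear"):
            diag = collinearity_diagnostics(np.column_stack([x, x, rng.standard_normal(25)]))
        assert np.isinf(diag.condition_number)

    def test_indices_match_independent_eigendecomposition(self, rng):
        X = rng.standard_normal((40, 5))
        diag = collinearity_diagnostics(X)
        Xs = X / np.linalg.norm(X, axis=0)
        mu = np.sort(np.linalg.eigvalsh(Xs.T @ Xs))[::-1]
        np.testing.assert_allclose(diag.condition_indices, np.sqrt(mu[0] / mu),
                                   rtol=1e-8)
        np.testing.assert_allclose(diag.correlation, np.corrcoef(X.T), atol=1e-12)

    def test_invariant_to_column_reordering(self, rng):
        X = rng.standard_normal((40, 4))
        d1 = collinearity_diagnostics(X)
        d2 = collinearity_diagnostics(X[:, ::-1])
        np.testing.assert_allclose(np.sort(d1.condition_indices),
                                   np.sort(d2.condition_indices), rtol=1e-10)
        assert d1.condition_number == pytest.approx(d2.condition_number)

    def test_zero_variance_column_named_in_error(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="intercept"):
            collinearity_diagnostics(X, names=("intercept", "slope"))


def test_ridge_ses_beat_unpenalized_in_most_replicates(rng):
    # high collinearity: the ridge fit's SEs should be smaller than the
    # lam=0 fit's in at least 95% of replicates (fixed seed)
    from rmelm import SimulationCell, simulate_dataset

    cell = SimulationCell(n=30, icc=0.2, rho=0.9, seed=9)
    wins = 0
    reps = 60
    for rep in range(reps):
        design, _ = simulate_dataset(cell, rep)
        ridge = fit(design, FitConfig(lambda_mode="auto"))
        plain = fit(design, FitConfig(lambda_mode="zero"))
        wins += np.all(ridge.se_beta <= plain.se_beta)
    assert wins / reps >= 0.95
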