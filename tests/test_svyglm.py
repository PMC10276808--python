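"""Pseudo-likelihood GLM engine and linearized design-based variance."""

import numpy as np
import pytest
from scipy.special import expit

from svycausal.sampler import DesignInfo
from svycausal.svyglm import (
    GLMConvergenceError,
    GLMFit,
    GLMSpec,
    fit_glm,
    fit_glm_arrays,
    wald_interval,
)

sm = pytest.importorskip("statsmodels.api")


def _logistic_data(n, rng, beta=(0.3, 0.5)):
    x = rng.normal(size=n)
    eta = beta[0] + beta[1] * x
    y = (rng.random(n) < expit(eta)).astype(float)
    return np.column_stack([np.ones(n), x]), y


class TestPointEstimation:
    def test_intercept_only_balanced_logistic(self):
        X = np.ones((4, 1))
        y = np.array([1.0, 0.0, 1.0, 0.0])
        fit = fit_glm_arrays(X, y, "binomial")
        assert fit.params[0] == pytest.approx(0.0, abs=1e-10)

    def test_poisson_offset_closed_form_rate(self, rng):
        n = 50
        t = rng.uniform(1, 5, n)
        y = rng.poisson(0.7 * t).astype(float)
        w = rng.uniform(0.5, 2, n)
        fit = fit_glm_arrays(np.ones((n, 1)), y, "poisson", weights=w, offset=np.log(t))
        expected = np.log((w * y).sum() / (w * t).sum())
        assert fit.params[0] == pytest.approx(expected, abs=1e-8)

    def test_weight_scale_invariance(self, rng):
        X, y = _logistic_data(300, rng)
        w = rng.uniform(0.5, 2, 300)
        f1 = fit_glm_arrays(X, y, "binomial", weights=w)
        f2 = fit_glm_arrays(X, y, "binomial", weights=10 * w)
        np.testing.assert_allclose(f1.params, f2.params, atol=1e-9)

    def test_matches_statsmodels_weighted_fit(self, rng):
        X, y = _logistic_data(400, rng)
        w = rng.uniform(0.5, 2, 400)
        mine = fit_glm_arrays(X, y, "binomial", weights=w)
        ref = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit()
        np.testing.assert_allclose(mine.params, ref.params, atol=1e-7)

    def test_separation_raises(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        y = (x > 0).astype(float)
        with pytest.raises(GLMConvergenceError):
            fit_glm_arrays(np.column_stack([np.ones(4), x]), y, "binomial")

    def test_invalid_inputs_rejected(self):
        X = np.ones((3, 1))
        with pytest.raises(ValueError):
            fit_glm_arrays(X, np.array([0.0, 1.0, 2.0]), "binomial")
        with pytest.raises(ValueError):
            fit_glm_arrays(X, np.array([0.0, 1.0, 0.0]), "binomial", weights=np.zeros(3))
        with pytest.raises(ValueError):
            GLMSpec("binomial", "y", offset="t")


class TestDesignCovariance:
    def test_equals_textbook_sandwich_single_stratum(self, rng):
        """One PSU per row, one stratum: linearized variance equals the
        robust sandwich computed independently (up to n/(n-1))."""
        n = 300
        X, y = _logistic_data(n, rng)
        d = DesignInfo(np.ones(n, dtype=int), np.arange(n), np.ones(n))
        fit = fit_glm_arrays(X, y, "binomial", design=d)
        # independent textbook computation
        mu = expit(X @ fit.params)
        u = (y - mu)[:, None] * X
        A = (X.T * (mu * (1 - mu))) @ X
        B = (n / (n - 1)) * (u.T @ u)
        V = np.linalg.inv(A) @ B @ np.linalg.inv(A)
        np.testing.assert_allclose(fit.cov, V, rtol=1e-8)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit(cov_type="HC0")
        np.testing.assert_allclose(fit.se, ref.bse * np.sqrt(n / (n - 1)), rtol=1e-6)

    def test_five_point_poisson_hand_computation(self):
        y = np.array([1.0, 0.0, 2.0, 1.0, 3.0])
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([np.ones(5), x])
        d = DesignInfo(np.ones(5, dtype=int), np.arange(5), np.ones(5))
        fit = fit_glm_arrays(X, y, "poisson", design=d)
        mu = np.exp(X @ fit.params)
        u = (y - mu)[:, None] * X
        A = (X.T * mu) @ X
        B = (5 / 4) * sum(np.outer(u[i] - u.mean(0), u[i] - u.mean(0)) for i in range(5))
        V = np.linalg.inv(A) @ B @ np.linalg.inv(A)
        np.testing.assert_allclose(fit.cov, V, rtol=1e-8)

    def test_psu_bootstrap_agreement_clustered(self, rng):
        """Linearized SEs agree with a bootstrap-of-PSUs oracle within 10%."""
        npsu, m = 60, 8
        psu = np.repeat(np.arange(npsu), m)
        u = rng.normal(0, 0.7, npsu)[psu]
        x = rng.normal(size=npsu * m)
        w = rng.uniform(0.5, 2.0, npsu * m)
        y = (rng.random(npsu * m) < expit(0.2 + 0.4 * x + u)).astype(float)
        X = np.column_stack([np.ones(npsu * m), x])
        d = DesignInfo(np.ones(npsu * m, dtype=int), psu, w)
        fit = fit_glm_arrays(X, y, "binomial", weights=w, design=d)
        boots = []
        brng = np.random.default_rng(2)
        for _ in range(300):
            pick = brng.integers(0, npsu, npsu)
            rows = (pick[:, None] * m + np.arange(m)).ravel()
            boots.append(fit_glm_arrays(X[rows], y[rows], "binomial", weights=w[rows]).params)
        bse = np.std(boots, axis=0, ddof=1) * np.sqrt((npsu - 1) / npsu)
        np.testing.assert_allclose(fit.se, bse, rtol=0.10)

    def test_design_se_exceeds_model_se_with_clustering(self, rng):
        npsu, m = 50, 10
        psu = np.repeat(np.arange(npsu), m)
        u = rng.normal(0, 1.0, npsu)[psu]
        x = rng.normal(size=npsu * m)
        y = (rng.random(npsu * m) < expit(0.2 + 0.3 * x + u)).astype(float)
        X = np.column_stack([np.ones(npsu * m), x])
        d = DesignInfo(np.ones(npsu * m, dtype=int), psu, np.ones(npsu * m))
        with_design = fit_glm_arrays(X, y, "binomial", design=d)
        model_only = fit_glm_arrays(X, y, "binomial")
        assert with_design.se[0] > model_only.se[0]

    def test_psu_duplication_leaves_point_estimates(self, rng):
        n = 100
        X, y = _logistic_data(n, rng)
        X2, y2 = np.vstack([X, X]), np.concatenate([y, y])
        d = DesignInfo(
            np.repeat([1, 2], n), np.concatenate([np.arange(n)] * 2), np.ones(2 * n)
        )
        f1 = fit_glm_arrays(X, y, "binomial")
        f2 = fit_glm_arrays(X2, y2, "binomial", design=d)
        np.testing.assert_allclose(f1.params, f2.params, atol=1e-8)

    def test_lonely_psu_warns(self, rng):
        n = 40
        X, y = _logistic_data(n, rng)
        strata = np.r_[np.zeros(n - 1, dtype=int), 9]
        d = DesignInfo(strata, np.arange(n), np.ones(n))
        with pytest.warns(RuntimeWarning, match="single PSU"):
            fit_glm_arrays(X, y, "binomial", design=d)


class TestWaldInterval:
    def test_standard_normal_quantiles(self):
        fit = GLMFit(
            params=np.array([0.0]), names=["b"], cov=np.array([[1.0]]),
            se=np.array([1.0]), family="binomial", cov_type="model",
            converged=True, n_iter=1, n_obs=10,
        )
        lo, hi = wald_interval(fit, "b")
        assert (lo, hi) == (pytest.approx(-1.95996, abs=1e-4), pytest.approx(1.95996, abs=1e-4))
        est, elo, ehi = fit.exp_effect("b")
        assert (elo, ehi) == (pytest.approx(0.1409, abs=1e-3), pytest.approx(7.0993, abs=1e-3))

    def test_zero_se_degenerate(self):
        fit = GLMFit(
            params=np.array([1.2]), names=["b"], cov=np.zeros((1, 1)),
            se=np.array([0.0]), family="binomial", cov_type="model",
            converged=True, n_iter=1, n_obs=10,
        )
        assert fit.wald_interval("b") == (1.2, 1.2)

    def test_coverage_calibration_intercept_only(self):
        """~95% of Wald CIs cover the true log-odds across repeated fits."""
        rng = np.random.default_rng(99)
        true = 0.4
        n, reps, cover = 2000, 1000, 0
        for _ in range(reps):
            y = (rng.random(n) < expit(true)).astype(float)
            fit = fit_glm_arrays(np.ones((n, 1)), y, "binomial")
            lo, hi = fit.wald_interval(0)
            cover += lo <= true <= hi
        assert cover / reps == pytest.approx(0.95, abs=0.02)


class TestFrameInterface:
    def test_fit_glm_from_dataframe(self, rng):
        import pandas as pd

        n = 200
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(0.2 + 0.4 * x)).astype(int)
        df = pd.DataFrame({"y": y, "x": x, "w": rng.uniform(0.5, 2, n)})
        fit = fit_glm(df, GLMSpec("binomial", "y", ["x"], weights="w"))
        ref = fit_glm_arrays(
            np.column_stack([np.ones(n), x]), y.astype(float), "binomial",
            weights=df["w"].to_numpy(),
        )
        np.testing.assert_allclose(fit.params, ref.params, atol=1e-10)
        assert fit.names == ["(Intercept)", "x"]
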