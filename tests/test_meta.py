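"""Multivariate meta-regression (REML) and BLUP shrinkage."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from heatmort.meta import (MultivariateMetaRegression, build_meta_predictors,
                           compute_blups, fit_meta_regression)
from heatmort.dlnm import CumulativeCurve


def univariate_reml_oracle(y, s2):
    """Direct 1-D bounded maximisation of the scalar REML log-likelihood."""
    def nll(tau2):
        w = 1.0 / (tau2 + s2)
        mu = np.sum(w * y) / np.sum(w)
        return 0.5 * (np.sum(np.log(tau2 + s2)) + np.sum(w * (y - mu) ** 2)
                      + np.log(np.sum(w)))
    res = optimize.minimize_scalar(nll, bounds=(1e-12, 100.0), method="bounded",
                                   options={"xatol": 1e-12})
    tau2 = res.x
    w = 1.0 / (tau2 + s2)
    return np.sum(w * y) / np.sum(w), tau2


def random_curves(n, v=3, seed=0, psi_scale=0.5, s_scale=0.3):
    rng = np.random.default_rng(seed)
    theta = rng.normal(size=v)
    A = rng.normal(size=(v, v))
    psi = psi_scale * (A @ A.T) / v
    Ls = np.linalg.cholesky(psi)
    Y, S = [], []
    for _ in range(n):
        B = rng.normal(size=(v, v))
        Si = s_scale * (B @ B.T) / v
        yi = theta + Ls @ rng.normal(size=v) + np.linalg.cholesky(Si) @ rng.normal(size=v)
        Y.append(yi)
        S.append(Si)
    return np.array(Y), np.array(S), theta, psi


class TestREML:
    def test_univariate_matches_closed_form_oracle(self):
        rng = np.random.default_rng(14)
        n = 15
        s2 = rng.uniform(0.3, 2.0, n)
        y = rng.normal(1.0, np.sqrt(1.2 + s2))
        mu_o, tau2_o = univariate_reml_oracle(y, s2)
        m = MultivariateMetaRegression().fit(np.ones((n, 1)), y[:, None],
                                             s2[:, None, None])
        assert m.theta_[0, 0] == pytest.approx(mu_o, abs=1e-6)
        assert m.psi_[0, 0] == pytest.approx(tau2_o, abs=1e-6)

    def test_no_heterogeneity_collapses_to_common_estimate(self):
        y = np.tile([0.7, -0.2, 1.1], (8, 1))
        S = [np.eye(3) * 0.4] * 8
        m = MultivariateMetaRegression().fit(np.ones((8, 1)), y, S)
        assert np.abs(m.psi_).max() < 1e-4
        assert np.allclose(m.theta_[0], [0.7, -0.2, 1.1], atol=1e-8)

    def test_psi_symmetric_psd_and_reml_no_worse_than_init(self):
        Y, S, *_ = random_curves(12, seed=2)
        m = MultivariateMetaRegression().fit(np.ones((12, 1)), Y, S)
        assert np.allclose(m.psi_, m.psi_.T)
        assert np.linalg.eigvalsh(m.psi_).min() >= -1e-10
        init = 0.1 * S.mean(axis=0)
        L0 = np.linalg.cholesky(init + 1e-10 * np.eye(3))
        par0 = L0[np.tril_indices(3)].copy()
        par0[np.cumsum(np.arange(3) + 1) - 1] = np.log(np.maximum(np.diag(L0), 1e-8))
        assert -m.loglik_reml_ <= m._reml_nll(par0, np.ones((12, 1)), Y, S) + 1e-8

    def test_permutation_invariance(self):
        Y, S, *_ = random_curves(10, seed=5)
        X = np.column_stack([np.ones(10), np.linspace(-1, 1, 10)])
        m1 = MultivariateMetaRegression().fit(X, Y, S)
        perm = np.random.default_rng(0).permutation(10)
        m2 = MultivariateMetaRegression().fit(X[perm], Y[perm], S[perm])
        assert np.allclose(m1.theta_, m2.theta_, atol=1e-6)
        assert np.allclose(m1.psi_, m2.psi_, atol=1e-5)

    def test_fixed_effect_ci_coverage_near_nominal(self):
        """Known Theta, Psi: the 95% Wald CI for each fixed effect should
        cover the truth at roughly nominal rate across replicates."""
        hits = total = 0
        for rep in range(200):
            Y, S, theta, _ = random_curves(14, v=2, seed=1000 + rep)
            m = MultivariateMetaRegression().fit(np.ones((14, 1)), Y, S)
            se = np.sqrt(np.diag(m.theta_cov_))
            est = m.theta_.T.ravel()   # outcome-major, matches theta_cov_
            hits += np.sum(np.abs(est - theta) <= 1.96 * se)
            total += len(theta)
        coverage = hits / total
        assert 0.90 <= coverage <= 0.985

    def test_singular_design_rejected(self):
        Y, S, *_ = random_curves(8, seed=3)
        X = np.column_stack([np.ones(8), np.ones(8)])
        with pytest.raises(ValueError, match="singular"):
            MultivariateMetaRegression().fit(X, Y, S)

    def test_too_few_locations_rejected(self):
        Y, S, *_ = random_curves(3, seed=3)
        X = np.column_stack([np.ones(3), np.linspace(0, 1, 3), np.linspace(1, 0, 3)])
        with pytest.raises(ValueError, match="locations"):
            MultivariateMetaRegression().fit(X, Y, S)


class TestBlup:
    def _fit(self, Y, S, X=None):
        X = np.ones((len(Y), 1)) if X is None else X
        return MultivariateMetaRegression().fit(X, Y, S)

    def test_scalar_shrinkage_factor_half(self):
        """Psi = 1, V = 1: BLUP sits exactly halfway between the location
        estimate and the pooled prediction."""
        m = MultivariateMetaRegression()
        m.psi_ = np.array([[1.0]])
        m.theta_ = np.array([[0.0]])
        m.theta_cov_ = np.zeros((1, 1))
        m.X_ = np.ones((3, 1))
        m.Y_ = np.array([[2.0], [0.0], [-2.0]])
        m.S_ = np.array([[[1.0]]] * 3)
        b, _ = m.blup()
        assert np.allclose(b.ravel(), [1.0, 0.0, -1.0])

    def test_vanishing_within_variance_returns_own_estimate(self):
        # limit identity of the BLUP formula itself, at a fixed full-rank Psi
        Y, *_ = random_curves(8, seed=7)
        m = MultivariateMetaRegression()
        m.psi_ = np.diag([0.5, 1.0, 2.0])
        m.theta_ = np.zeros((1, 3))
        m.theta_cov_ = np.zeros((3, 3))
        m.X_ = np.ones((8, 1))
        m.Y_ = Y
        m.S_ = np.array([np.eye(3) * 1e-12] * 8)
        b, _ = m.blup()
        assert np.allclose(b, Y, atol=1e-9)

    def test_vanishing_psi_returns_fixed_effect_prediction(self):
        m = MultivariateMetaRegression()
        m.psi_ = np.zeros((2, 2))
        m.theta_ = np.array([[0.5, -0.5]])
        m.theta_cov_ = np.zeros((2, 2))
        m.X_ = np.ones((4, 1))
        m.Y_ = np.random.default_rng(1).normal(size=(4, 2))
        m.S_ = np.array([np.eye(2)] * 4)
        b, c = m.blup()
        assert np.allclose(b, np.tile([0.5, -0.5], (4, 1)))
        assert np.allclose(c, 0.0)

    def test_scalar_blup_between_estimate_and_pooled(self):
        rng = np.random.default_rng(9)
        y = rng.normal(0, 2, 12)[:, None]
        S = rng.uniform(0.2, 1.5, 12)[:, None, None]
        m = self._fit(y, S)
        b, _ = m.blup()
        pooled = m.theta_[0, 0]
        lo = np.minimum(y.ravel(), pooled)
        hi = np.maximum(y.ravel(), pooled)
        assert ((b.ravel() >= lo - 1e-12) & (b.ravel() <= hi + 1e-12)).all()


class TestIntegration:
    def test_meta_predictor_design(self):
        md = pd.DataFrame({
            "location_id": ["a", "b", "c", "d"],
            "country": ["x"] * 4,
            "region": ["N", "S", "N", "S"],
            "climate_class": ["t", "t", "t", "t"],   # constant: dropped
            "gdp_pc": [1e4, 2e4, 3e4, 4e4],
            "lon": [0] * 4, "lat": [0] * 4,
        })
        X = build_meta_predictors(md)
        assert "intercept" in X.columns
        assert not any(c.startswith("climate") for c in X.columns)
        assert X["log_gdp_pc"].abs().max() < 3  # standardised

    def test_blup_curves_get_fresh_mmt(self):
        rng = np.random.default_rng(4)
        knots = np.array([8.0, 15.0, 20.0])
        curves = {}
        for i in range(6):
            beta = rng.normal(0, 0.2, 4)
            curves[f"loc{i}"] = CumulativeCurve(
                beta=beta, vcov=np.eye(4) * 0.01, knots=knots, boundary=(0.0, 30.0),
                temp_percentiles={"p1": 1.0, "p50": 15.0, "p99": 29.0})
        X = pd.DataFrame({"intercept": np.ones(6)},
                         index=[f"loc{i}" for i in range(6)])
        model = fit_meta_regression(curves, X)
        blups = compute_blups(model, curves, X)
        assert set(blups) == set(curves)
        assert all(b.mmt is not None for b in blups.values())
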