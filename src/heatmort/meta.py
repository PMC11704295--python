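"""Second-stage pooling: multivariate meta-regression and BLUPs.

Location-specific reduced coefficient vectors ``beta_i`` (with within-
location covariances ``S_i``) are pooled under the random-effects model

    beta_i ~ N(Theta^T x_i, Psi + S_i)

where ``x_i`` are location-level meta-predictors (region and climate-class
indicators, log GDP per capita, mean and range of temperature) and ``Psi``
is the between-location covariance.  ``Psi`` is estimated by REML through a
Cholesky parameterisation, fixed effects by generalised least squares at
each ``Psi``.  Best linear unbiased predictions shrink each location's
estimate toward its meta-regression prediction in proportion to the
within- versus between-location covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .dlnm import CumulativeCurve, find_mmt

__all__ = [
    "build_meta_predictors",
    "MultivariateMetaRegression",
    "fit_meta_regression",
    "compute_blups",
]


def build_meta_predictors(metadata: pd.DataFrame, daily: pd.DataFrame | None = None
                          ) -> pd.DataFrame:
    """Design matrix of meta-predictors, one row per location.

    Categorical region/climate columns are one-hot encoded (first level
    dropped); log GDP per capita and the location's mean and range of
    observed temperature are standardised.  Columns with zero variance
    (e.g. a single region) are dropped rather than left collinear.
    """
    md = metadata.set_index("location_id")
    X = pd.DataFrame(index=md.index)
    X["intercept"] = 1.0
    for col in ("region", "climate_class"):
        if col in md:
            X = X.join(pd.get_dummies(md[col], prefix=col, drop_first=True, dtype=float))
    if "gdp_pc" in md:
        X["log_gdp_pc"] = np.log(md["gdp_pc"])
    if daily is not None:
        g = daily.groupby("location_id")["tmean"]
        X["tmean_avg"] = g.mean()
        X["tmean_range"] = g.max() - g.min()
    for col in X.columns:
        if col == "intercept":
            continue
        sd = X[col].std(ddof=0)
        if sd < 1e-12:
            X = X.drop(columns=col)
        else:
            X[col] = (X[col] - X[col].mean()) / sd
    return X


def _chol_to_psi(theta: np.ndarray, v: int) -> np.ndarray:
    L = np.zeros((v, v))
    idx = np.tril_indices(v)
    L[idx] = theta
    L[np.diag_indices(v)] = np.exp(np.clip(np.diag(L), -30, 30))
    return L @ L.T


class MultivariateMetaRegression:
    """REML multivariate meta-regression estimator (scikit-learn style).

    Fitted attributes: ``theta_`` (q x v fixed-effect matrix), ``psi_``
    (v x v between-location covariance), ``theta_cov_`` (qv x qv covariance
    of vec(theta), outcome-major), ``loglik_reml_``, ``converged_``.
    """

    def __init__(self, max_iter: int = 500, tol: float = 1e-10):
        self.max_iter = max_iter
        self.tol = tol

    def get_params(self, deep: bool = True) -> dict:
        return {"max_iter": self.max_iter, "tol": self.tol}

    def set_params(self, **params) -> "MultivariateMetaRegression":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- REML machinery -----------------------------------------------------
    @staticmethod
    def _gls(X, Y, S, psi):
        """Fixed effects by GLS at a given Psi; returns (theta qxv, cov, extras)."""
        n, q = X.shape
        v = Y.shape[1]
        A = np.zeros((q * v, q * v))
        b = np.zeros(q * v)
        Wi = np.empty((n, v, v))
        for i in range(n):
            Wi[i] = np.linalg.inv(psi + S[i])
            Zi = np.kron(np.eye(v), X[i][None, :])   # (v, q*v), vec outcome-major
            A += Zi.T @ Wi[i] @ Zi
            b += Zi.T @ Wi[i] @ Y[i]
        cov = np.linalg.inv(A)
        theta_vec = cov @ b
        return theta_vec.reshape(v, q).T, cov, (A, Wi)

    def _reml_nll(self, par, X, Y, S):
        v = Y.shape[1]
        psi = _chol_to_psi(par, v)
        try:
            theta, _, (A, Wi) = self._gls(X, Y, S, psi)
        except np.linalg.LinAlgError:
            return 1e12
        nll = 0.0
        for i in range(len(Y)):
            r = Y[i] - theta.T @ X[i]
            sign, logdet = np.linalg.slogdet(psi + S[i])
            if sign <= 0:
                return 1e12
            nll += 0.5 * (logdet + r @ Wi[i] @ r)
        sign, logdet = np.linalg.slogdet(A)
        nll += 0.5 * logdet
        return nll if np.isfinite(nll) else 1e12

    def fit(self, X, Y, S) -> "MultivariateMetaRegression":
        """Fit to per-location outcomes.

        Parameters
        ----------
        X : (n, q) array or DataFrame — meta-predictor design (with intercept).
        Y : (n, v) array — reduced coefficient vectors, one row per location.
        S : sequence of n (v, v) arrays — within-location covariances.
        """
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        S = np.asarray(S, dtype=float)
        n, q = X.shape
        v = Y.shape[1]
        if n < max(q + 1, 3):
            raise ValueError(f"need at least {max(q + 1, 3)} locations for {q} predictors")
        rank = np.linalg.matrix_rank(X)
        if rank < q:
            raise ValueError("singular meta-predictor design (collinear columns)")

        # init: Psi = 0.1 * mean within-location covariance
        psi0 = 0.1 * S.mean(axis=0)
        L0 = np.linalg.cholesky(psi0 + 1e-10 * np.eye(v))
        par0 = L0[np.tril_indices(v)].copy()
        L0d = np.maximum(np.diag(L0), 1e-8)
        par0[np.cumsum(np.arange(v) + 1) - 1] = np.log(L0d)

        nll0 = self._reml_nll(par0, X, Y, S)
        res = optimize.minimize(self._reml_nll, par0, args=(X, Y, S),
                                method="L-BFGS-B",
                                options={"maxiter": self.max_iter, "ftol": self.tol,
                                         "gtol": 1e-9})
        polish = optimize.minimize(self._reml_nll, res.x, args=(X, Y, S),
                                   method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-12,
                                            "maxiter": 2000})
        if polish.fun < res.fun:
            res.x, res.fun = polish.x, polish.fun
        if res.fun > nll0 + 1e-8:
            res.x, res.fun = par0, nll0  # never worse than the initialisation
        self.converged_ = bool(res.success) or res.fun <= nll0
        self.psi_ = _chol_to_psi(res.x, v)
        self.theta_, self.theta_cov_, _ = self._gls(X, Y, S, self.psi_)
        self.loglik_reml_ = -float(res.fun)
        self.X_, self.Y_, self.S_ = X, Y, S
        self.n_locations_, self.n_outcomes_, self.n_predictors_ = n, v, q
        # residual df for small-sample (t-quantile) intervals on pooled and
        # BLUP quantities, in the spirit of Knapp-Hartung adjustments
        self.df_resid_ = n - q
        return self

    def predict(self, X) -> np.ndarray:
        """Fixed-effect (population-average) prediction for rows of X."""
        return np.asarray(X, dtype=float) @ self.theta_

    def blup(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-location BLUP coefficients and covariances.

        beta_blup_i = X_i Theta + Psi (Psi + S_i)^{-1} (beta_i - X_i Theta);
        the covariance combines the conditional (posterior) covariance of
        the random effect, S_i (Psi + S_i)^{-1} Psi, with the propagated
        fixed-effect uncertainty.
        """
        n, v = self.Y_.shape
        blups = np.empty((n, v))
        covs = np.empty((n, v, v))
        for i in range(n):
            W = np.linalg.inv(self.psi_ + self.S_[i])
            A = self.psi_ @ W
            fixed = self.theta_.T @ self.X_[i]
            blups[i] = fixed + A @ (self.Y_[i] - fixed)
            Zi = np.kron(np.eye(v), self.X_[i][None, :])
            IA = np.eye(v) - A
            cov = self.S_[i] @ W @ self.psi_ + IA @ (Zi @ self.theta_cov_ @ Zi.T) @ IA.T
            covs[i] = (cov + cov.T) / 2.0
        return blups, covs


def fit_meta_regression(curves: dict[str, CumulativeCurve], X: pd.DataFrame
                        ) -> MultivariateMetaRegression:
    """Pool first-stage cumulative curves; curves must share one basis."""
    ids = list(X.index)
    missing = [i for i in ids if i not in curves]
    if missing:
        raise ValueError(f"no first-stage curve for locations: {missing}")
    k0 = np.asarray(curves[ids[0]].knots)
    for i in ids[1:]:
        if np.asarray(curves[i].knots).shape != k0.shape:
            raise ValueError("curves do not share a basis specification")
    Y = np.array([curves[i].beta for i in ids])
    S = [curves[i].vcov for i in ids]
    return MultivariateMetaRegression().fit(X.to_numpy(dtype=float), Y, S)


def compute_blups(model: MultivariateMetaRegression,
                  curves: dict[str, CumulativeCurve], X: pd.DataFrame
                  ) -> dict[str, CumulativeCurve]:
    """BLUP curves with MMT re-found on each shrunken curve."""
    blups, covs = model.blup()
    out = {}
    for i, loc in enumerate(X.index):
        base = curves[loc]
        c = CumulativeCurve(beta=blups[i], vcov=covs[i], knots=base.knots,
                            boundary=base.boundary,
                            temp_percentiles=dict(base.temp_percentiles))
        c.mmt = find_mmt(c)
        out[loc] = c
    return out
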