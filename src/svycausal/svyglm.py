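"""Pseudo-likelihood GLMs with design-based (Taylor linearization) variance.

Point estimation solves the weighted score equations
``sum_i w_i (y_i - mu_i) x_i = 0`` by IRLS for the binomial-logit and
Poisson-log (with offset) families; coefficients are invariant to positive
rescaling of the weights.  Variance estimation for design-weighted analyses
uses the with-replacement first-stage linearization for stratified cluster
samples: the sandwich ``V = A^-1 B A^-1`` where ``A`` is the weighted
information and ``B`` accumulates the between-PSU covariance of weighted
score totals within strata with the usual ``n_h / (n_h - 1)`` factor.
Unweighted (or design-free) fits report the model-based covariance
``A^-1`` instead.

Strata that retain a single PSU (possible after matching prunes rows) are
handled with the "adjust" convention: the lonely PSU's score total is
centered at the grand mean of all PSU totals, and a warning is emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .sampler import DesignInfo

__all__ = [
    "GLMSpec",
    "GLMFit",
    "GLMConvergenceError",
    "fit_glm",
    "fit_glm_arrays",
    "design_covariance",
    "wald_interval",
]

IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100


class GLMConvergenceError(RuntimeError):
    """IRLS failed to converge (including apparent perfect separation)."""


@dataclass
class GLMSpec:
    """Declarative model spec: family, response, covariates, offset, weights.

    ``covariates`` may be empty (intercept-only).  ``weights`` may name a
    column or carry an array; ``offset`` (a column name, log scale) is only
    valid for the poisson family.  If ``design`` is given the covariance is
    design-based, otherwise model-based.
    """

    family: str
    response: str
    covariates: list[str] = field(default_factory=list)
    offset: str | None = None
    weights: str | np.ndarray | None = None
    design: DesignInfo | None = None

    def __post_init__(self) -> None:
        if self.family not in ("binomial", "poisson"):
            raise ValueError("family must be 'binomial' or 'poisson'")
        if self.offset is not None and self.family != "poisson":
            raise ValueError("offset is only supported with the poisson family")


@dataclass
class GLMFit:
    """Fitted coefficients with covariance and Wald intervals."""

    params: np.ndarray
    names: list[str]
    cov: np.ndarray
    se: np.ndarray
    family: str
    cov_type: str  # "model" | "linearized"
    converged: bool
    n_iter: int
    n_obs: int
    fitted: np.ndarray | None = None

    def index(self, name: str) -> int:
        return self.names.index(name)

    def wald_interval(self, name: str | int, level: float = 0.95) -> tuple[float, float]:
        i = name if isinstance(name, int) else self.index(name)
        z = norm.ppf(0.5 + level / 2.0)
        lo = self.params[i] - z * self.se[i]
        hi = self.params[i] + z * self.se[i]
        return float(lo), float(hi)

    def exp_effect(self, name: str | int, level: float = 0.95):
        """Exponentiated coefficient with CI (odds/rate-ratio scale)."""
        i = name if isinstance(name, int) else self.index(name)
        lo, hi = self.wald_interval(i, level)
        return float(np.exp(self.params[i])), float(np.exp(lo)), float(np.exp(hi))

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "cov_type": self.cov_type,
            "n_obs": self.n_obs,
            "coefficients": {
                nm: {"estimate": float(b), "se": float(s), "ci": list(self.wald_interval(i))}
                for i, (nm, b, s) in enumerate(zip(self.names, self.params, self.se))
            },
        }


def wald_interval(fit: GLMFit, coefficient: str | int, level: float = 0.95):
    """Wald interval for one coefficient (module-level convenience)."""
    if not fit.converged:
        raise GLMConvergenceError("interval requested from a non-converged fit")
    return fit.wald_interval(coefficient, level)


def _irls(X, y, family, w, offset):
    n, p = X.shape
    beta = np.zeros(p)
    # one-step intercept start
    sw = w.sum()
    if family == "binomial":
        ybar = float(np.clip((w * y).sum() / sw, 1e-6, 1 - 1e-6))
        beta[0] = np.log(ybar / (1 - ybar))
    else:
        t = np.exp(offset) if offset is not None else 1.0
        rate = (w * y).sum() / (w * t).sum()
        beta[0] = np.log(max(rate, 1e-12))

    for it in range(1, IRLS_MAX_ITER + 1):
        eta = X @ beta
        if offset is not None:
            eta = eta + offset
        if family == "binomial":
            mu = expit(eta)
            var = mu * (1.0 - mu)
        else:
            mu = np.exp(np.clip(eta, -700, 700))
            var = mu
        wk = w * var
        # working response relative to the linear predictor without offset
        resid = y - mu
        XtW = X.T * wk
        A = XtW @ X
        score = X.T @ (w * resid)
        try:
            delta = np.linalg.solve(A, score)
        except np.linalg.LinAlgError as exc:
            raise GLMConvergenceError(
                "singular weighted information (possible separation)"
            ) from exc
        beta = beta + delta
        if np.max(np.abs(beta)) > 1e3:
            raise GLMConvergenceError("diverging coefficients (possible separation)")
        if np.max(np.abs(delta)) < IRLS_TOL:
            return beta, A, mu, it, True
    raise GLMConvergenceError(f"IRLS did not converge in {IRLS_MAX_ITER} iterations")


def fit_glm_arrays(
    X: np.ndarray,
    y: np.ndarray,
    family: str,
    weights: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    design: DesignInfo | None = None,
    names: list[str] | None = None,
    keep_fitted: bool = False,
) -> GLMFit:
    """Fit a weighted GLM from design matrix ``X`` (first column = intercept)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if family == "binomial" and not np.all((y == 0) | (y == 1)):
        raise ValueError("binomial response must be binary")
    if family == "poisson" and np.any(y < 0):
        raise ValueError("poisson response must be nonnegative")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be nonnegative and not all zero")

    beta, A, mu, n_iter, conv = _irls(X, y, family, w, offset)

    if design is not None:
        cov = design_covariance_arrays(X, y, mu, w, A, design)
        cov_type = "linearized"
    else:
        cov = np.linalg.inv(A)
        cov_type = "model"
    cov = 0.5 * (cov + cov.T)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    if names is None:
        names = ["(Intercept)"] + [f"x{i}" for i in range(1, p)]
    return GLMFit(
        params=beta, names=list(names), cov=cov, se=se, family=family,
        cov_type=cov_type, converged=conv, n_iter=n_iter, n_obs=n,
        fitted=mu if keep_fitted else None,
    )


def fit_glm(data: pd.DataFrame, spec: GLMSpec, keep_fitted: bool = False) -> GLMFit:
    """Fit the model described by ``spec`` on a flat table."""
    n = len(data)
    cols = [np.ones(n)] + [data[c].to_numpy(dtype=float) for c in spec.covariates]
    X = np.column_stack(cols)
    y = data[spec.response].to_numpy(dtype=float)
    offset = data[spec.offset].to_numpy(dtype=float) if spec.offset else None
    if isinstance(spec.weights, str):
        w = data[spec.weights].to_numpy(dtype=float)
    else:
        w = None if spec.weights is None else np.asarray(spec.weights, dtype=float)
    names = ["(Intercept)"] + list(spec.covariates)
    return fit_glm_arrays(
        X, y, spec.family, weights=w, offset=offset, design=spec.design,
        names=names, keep_fitted=keep_fitted,
    )


def design_covariance_arrays(
    X: np.ndarray,
    y: np.ndarray,
    mu: np.ndarray,
    w: np.ndarray,
    A: np.ndarray,
    design: DesignInfo,
) -> np.ndarray:
    """Taylor-linearization sandwich from per-row score contributions.

    Scores ``u_i = w_i (y_i - mu_i) x_i`` (canonical links) are summed to
    PSU totals; ``B`` is the stratified between-PSU covariance of those
    totals with factor ``n_h / (n_h - 1)``; the covariance is
    ``A^-1 B A^-1``.
    """
    u = (w * (y - mu))[:, None] * X
    strata = np.asarray(design.strata)
    psu = np.asarray(design.psu)
    # group rows by (stratum, psu)
    key = strata.astype(np.int64) * (psu.max() + 1) + psu.astype(np.int64)
    groups, ginv = np.unique(key, return_inverse=True)
    g_strata_idx = np.zeros(groups.size, dtype=np.int64)
    g_strata_idx[ginv] = np.arange(len(strata))  # one representative row per group
    psu_tot = np.zeros((groups.size, X.shape[1]))
    np.add.at(psu_tot, ginv, u)
    psu_stratum = strata[g_strata_idx]

    strat_labels, sinv = np.unique(psu_stratum, return_inverse=True)
    n_h = np.bincount(sinv)
    p = X.shape[1]
    B = np.zeros((p, p))
    lonely = n_h == 1
    if np.any(lonely):
        warnings.warn(
            f"{int(lonely.sum())} stratum(s) contain a single PSU; "
            "centering at the grand mean ('adjust' convention)",
            RuntimeWarning,
            stacklevel=2,
        )
    grand_mean = psu_tot.mean(axis=0)
    # stratum means of PSU totals
    smean = np.zeros((strat_labels.size, p))
    np.add.at(smean, sinv, psu_tot)
    smean /= n_h[:, None]
    for h in range(strat_labels.size):
        tot_h = psu_tot[sinv == h]
        if n_h[h] == 1:
            d = tot_h[0] - grand_mean
            B += np.outer(d, d)
        else:
            d = tot_h - smean[h]
            B += (n_h[h] / (n_h[h] - 1.0)) * (d.T @ d)
    Ainv = np.linalg.inv(A)
    return Ainv @ B @ Ainv


def design_covariance(data: pd.DataFrame, spec: GLMSpec, fit: GLMFit) -> np.ndarray:
    """Recompute the linearized covariance for an existing fit."""
    if spec.design is None:
        raise ValueError("spec must carry DesignInfo")
    n = len(data)
    cols = [np.ones(n)] + [data[c].to_numpy(dtype=float) for c in spec.covariates]
    X = np.column_stack(cols)
    y = data[spec.response].to_numpy(dtype=float)
    offset = data[spec.offset].to_numpy(dtype=float) if spec.offset else None
    eta = X @ fit.params
    if offset is not None:
        eta = eta + offset
    mu = expit(eta) if spec.family == "binomial" else np.exp(eta)
    if isinstance(spec.weights, str):
        w = data[spec.weights].to_numpy(dtype=float)
    elif spec.weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(spec.weights, dtype=float)
    wvar = mu * (1 - mu) if spec.family == "binomial" else mu
    A = (X.T * (w * wvar)) @ X
    return design_covariance_arrays(X, y, mu, w, A, spec.design)
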