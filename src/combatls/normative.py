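"""Covariate-indexed BCCG normative models producing centile and Z-scores.

The three distribution parameters are regressed on covariates with standard
links — log for mu, log for sigma, identity for nu — and each linear
predictor always carries an intercept:

    log(mu_j)   = x_mu_j'    beta_mu
    log(sigma_j)= x_sigma_j' beta_sigma
    nu_j        = x_nu_j'    beta_nu        (default: intercept only)

Fitting maximizes the (optionally spline-penalized) BCCG log-likelihood
jointly over all coefficient blocks with L-BFGS-B and an analytic gradient.
A non-converged fit is flagged and refuses to score subjects rather than
silently returning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtri
from sklearn.base import BaseEstimator

from .bccg import bccg_cdf, bccg_quantile
from .design import DesignInfo, Linear, Poly, Term, build_design


class NotConvergedError(RuntimeError):
    """Raised when scoring is attempted with a non-converged normative fit."""


@dataclass
class NormativeSpec:
    """Covariate term lists for the three BCCG parameters.

    The default emulates an adult-cohort brain chart: cubic polynomial in age
    plus linear sex for both mu and log-sigma, constant nu.
    """

    mu_terms: list[Term] = field(
        default_factory=lambda: [Poly("age", 3), Linear("sex")]
    )
    sigma_terms: list[Term] = field(
        default_factory=lambda: [Poly("age", 3), Linear("sex")]
    )
    nu_terms: list[Term] = field(default_factory=list)


def _nll_and_grad(theta, y, log_y, xm, xs, xn, pens):
    pm, ps = xm.shape[1], xs.shape[1]
    bm, bs, bn = theta[:pm], theta[pm:pm + ps], theta[pm + ps:]
    log_mu = xm @ bm
    log_sg = np.clip(xs @ bs, -300, 300)
    nu = xn @ bn
    sigma = np.exp(log_sg)
    t = log_y - log_mu
    nut = nu * t
    small = np.abs(nu) < 1e-5
    safe_nu = np.where(small, 1.0, nu)
    e_nut = np.exp(np.clip(nut, -700, 700))
    z = np.where(small, (t + 0.5 * nu * t**2) / sigma,
                 np.expm1(np.clip(nut, -700, 700)) / (safe_nu * sigma))
    ll = (nu - 1.0) * log_y - nu * log_mu - log_sg - 0.5 * z**2
    # gradients wrt the linear predictors
    dl_dlogmu = -nu + z * e_nut / sigma
    dl_dlogsg = z**2 - 1.0
    dz_dnu = np.where(
        small,
        (0.5 * t**2 + nu * t**3 / 3.0) / sigma,
        t * e_nut / (safe_nu * sigma) - z / safe_nu,
    )
    dl_dnu = t - z * dz_dnu
    nll = -float(np.sum(ll))
    g = -np.concatenate([xm.T @ dl_dlogmu, xs.T @ dl_dlogsg, xn.T @ dl_dnu])
    for sl, pen, lam in pens:
        nll += 0.5 * lam * float(theta[sl] @ pen @ theta[sl])
        g[sl] += lam * (pen @ theta[sl])
    return nll, g


class BCCGNormativeModel(BaseEstimator):
    """Normative growth-chart model for one feature under the BCCG family.

    Parameters
    ----------
    mu_terms, sigma_terms, nu_terms : term lists or None
        Covariate models for the three parameters (intercepts are always
        added).  Defaults follow :class:`NormativeSpec`.
    smooth_lambda : float
        Fixed penalty weight for any P-spline terms.
    max_iter : int
        L-BFGS iteration cap; exceeding it flags the fit as non-converged.

    Fitted attributes: ``coef_mu_``, ``coef_sigma_``, ``coef_nu_``,
    ``loglik_``, ``converged_``, ``n_obs_``.
    """

    def __init__(
        self,
        mu_terms=None,
        sigma_terms=None,
        nu_terms=None,
        smooth_lambda: float = 1.0,
        max_iter: int = 200,
        tol: float = 1e-9,
    ):
        self.mu_terms = mu_terms
        self.sigma_terms = sigma_terms
        self.nu_terms = nu_terms
        self.smooth_lambda = smooth_lambda
        self.max_iter = max_iter
        self.tol = tol

    def _spec(self) -> NormativeSpec:
        spec = NormativeSpec()
        if self.mu_terms is not None:
            spec.mu_terms = list(self.mu_terms)
        if self.sigma_terms is not None:
            spec.sigma_terms = list(self.sigma_terms)
        if self.nu_terms is not None:
            spec.nu_terms = list(self.nu_terms)
        return spec

    # -- fitting -----------------------------------------------------------
    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float).ravel()
        if np.any(y <= 0):
            raise ValueError(
                "BCCG requires strictly positive responses; shift or log-scale "
                "the feature first"
            )
        if np.var(y) == 0:
            raise ValueError("response is constant; normative fit is degenerate")
        spec = self._spec()
        n_coef_budget = 3 + len(spec.mu_terms) + len(spec.sigma_terms)
        if len(y) < 10 * n_coef_budget:
            warnings.warn(
                f"n = {len(y)} is small for the requested model; estimates may "
                "be unstable",
                stacklevel=2,
            )
        xm, self.mu_info_ = build_design(X, spec.mu_terms, include_intercept=True)
        xs, self.sigma_info_ = build_design(X, spec.sigma_terms, include_intercept=True)
        xn, self.nu_info_ = build_design(X, spec.nu_terms, include_intercept=True)
        pm, ps, pn = xm.shape[1], xs.shape[1], xn.shape[1]

        pens = []
        for info, offset in ((self.mu_info_, 0), (self.sigma_info_, pm),
                             (self.nu_info_, pm + ps)):
            for sl, pen in info.penalty_blocks:
                pens.append((slice(offset + sl.start, offset + sl.stop), pen,
                             self.smooth_lambda))

        log_y = np.log(y)
        bm0, *_ = np.linalg.lstsq(xm, log_y, rcond=None)
        r = log_y - xm @ bm0
        bs0 = np.zeros(ps)
        bs0[0] = np.log(max(np.std(r), 1e-6))
        bn0 = np.zeros(pn)
        bn0[0] = 1.0
        theta0 = np.concatenate([bm0, bs0, bn0])

        res = minimize(
            _nll_and_grad,
            theta0,
            args=(y, log_y, xm, xs, xn, pens),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": self.tol,
                     "gtol": 1e-7 * len(y)},
        )
        theta = res.x
        self.coef_mu_ = theta[:pm]
        self.coef_sigma_ = theta[pm:pm + ps]
        self.coef_nu_ = theta[pm + ps:]
        self.loglik_ = -float(
            _nll_and_grad(theta, y, log_y, xm, xs, xn, [])[0]
        )
        self.penalized_loglik_ = -float(res.fun)
        self.n_obs_ = len(y)
        self.n_iter_ = int(res.nit)
        # line-search hiccups at an essentially stationary point still count
        grad_ok = float(np.max(np.abs(res.jac))) < 1e-4 * len(y)
        self.converged_ = bool(res.success) or grad_ok
        self.train_ranges_ = {
            c: (float(X[c].min()), float(X[c].max()))
            for c in X.columns
            if np.issubdtype(np.asarray(X[c]).dtype, np.number)
        }
        if not self.converged_:
            warnings.warn(
                f"normative fit did not converge ({res.message}); scoring is "
                "refused",
                stacklevel=2,
            )
        return self

    # -- prediction --------------------------------------------------------
    def _check_scoreable(self, force: bool) -> None:
        if not hasattr(self, "coef_mu_"):
            raise RuntimeError("BCCGNormativeModel is not fitted")
        if not self.converged_ and not force:
            raise NotConvergedError(
                "fit flagged as non-converged; refusing to score "
                "(pass force=True to override)"
            )

    def _warn_extrapolation(self, X: pd.DataFrame) -> None:
        for c, (lo, hi) in self.train_ranges_.items():
            if c in X.columns:
                vals = np.asarray(X[c], dtype=float)
                if np.any(vals < lo) or np.any(vals > hi):
                    warnings.warn(
                        f"covariate '{c}' outside the training support "
                        f"[{lo:g}, {hi:g}]; extrapolating",
                        stacklevel=3,
                    )

    def predict_params(self, X: pd.DataFrame, force: bool = False):
        """Per-subject (mu, sigma, nu)."""
        self._check_scoreable(force)
        self._warn_extrapolation(X)
        mu = np.exp(self.mu_info_.transform(X) @ self.coef_mu_)
        sigma = np.exp(self.sigma_info_.transform(X) @ self.coef_sigma_)
        nu = self.nu_info_.transform(X) @ self.coef_nu_
        return mu, sigma, nu

    def predict_centile(self, y, X: pd.DataFrame, force: bool = False) -> pd.DataFrame:
        """Centile in (0, 1) and the matching Z-score for each subject."""
        mu, sigma, nu = self.predict_params(X, force=force)
        cent = bccg_cdf(np.asarray(y, dtype=float).ravel(), mu, sigma, nu)
        cent = np.clip(cent, 1e-15, 1 - 1e-15)
        return pd.DataFrame(
            {"centile": cent, "zscore": ndtri(cent)},
            index=X.index if hasattr(X, "index") else None,
        )

    def predict_quantile_curves(
        self, X: pd.DataFrame, qs=(0.25, 0.5, 0.75), force: bool = False
    ) -> pd.DataFrame:
        """Feature values at the requested centiles for each covariate row."""
        mu, sigma, nu = self.predict_params(X, force=force)
        out = {}
        for q in qs:
            out[f"q{q:g}"] = bccg_quantile(q, mu, sigma, nu)
        return pd.DataFrame(out, index=X.index if hasattr(X, "index") else None)


    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "coef_mu": self.coef_mu_.tolist(),
            "coef_sigma": self.coef_sigma_.tolist(),
            "coef_nu": self.coef_nu_.tolist(),
            "mu_design": self.mu_info_.to_dict(),
            "sigma_design": self.sigma_info_.to_dict(),
            "nu_design": self.nu_info_.to_dict(),
            "loglik": self.loglik_,
            "converged": self.converged_,
            "n_obs": self.n_obs_,
            "train_ranges": self.train_ranges_,
            "smooth_lambda": self.smooth_lambda,
        }

    def save(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "BCCGNormativeModel":
        model = cls(smooth_lambda=d["smooth_lambda"])
        model.coef_mu_ = np.asarray(d["coef_mu"])
        model.coef_sigma_ = np.asarray(d["coef_sigma"])
        model.coef_nu_ = np.asarray(d["coef_nu"])
        model.mu_info_ = DesignInfo.from_dict(d["mu_design"])
        model.sigma_info_ = DesignInfo.from_dict(d["sigma_design"])
        model.nu_info_ = DesignInfo.from_dict(d["nu_design"])
        model.loglik_ = d["loglik"]
        model.converged_ = d["converged"]
        model.n_obs_ = d["n_obs"]
        model.train_ranges_ = {k: tuple(v) for k, v in d["train_ranges"].items()}
        return model

    @classmethod
    def load(cls, path) -> "BCCGNormativeModel":
        import json

        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_normative(
    y, covariates: pd.DataFrame, spec: NormativeSpec | None = None, **kwargs
) -> BCCGNormativeModel:
    """Fit a BCCG normative model for one feature."""
    spec = spec or NormativeSpec()
    model = BCCGNormativeModel(
        mu_terms=spec.mu_terms,
        sigma_terms=spec.sigma_terms,
        nu_terms=spec.nu_terms,
        **kwargs,
    )
    return model.fit(covariates, y)


def predict_centile(model: BCCGNormativeModel, y, covariates: pd.DataFrame) -> pd.DataFrame:
    return model.predict_centile(y, covariates)


def predict_quantile_curves(
    model: BCCGNormativeModel, grid: pd.DataFrame, qs=(0.25, 0.5, 0.75)
) -> pd.DataFrame:
    return model.predict_quantile_curves(grid, qs)
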