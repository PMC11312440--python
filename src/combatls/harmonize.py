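"""ComBat-family batch-effect harmonization: linear ComBat, ComBat-GAM, ComBatLS.

All three methods share one location-scale model per feature k, site i,
subject j:

    y_ijk = alpha_k + f_k(x_ij) + gamma_ik + delta_ik * e_ijk

with additive site offsets gamma constrained by sum_i n_i * gamma_ik = 0 and
multiplicative site scalings delta.  They differ in the covariate model:

* ``combat_nocov`` — no covariates;
* ``combat``      — linear age + sex in the mean;
* ``combat_gam``  — penalized cubic spline for age + linear sex in the mean;
* ``combat_ls``   — ComBat-GAM's mean model plus a log-linear model of the
  error SD on covariates, ``log(sigma_ijk) = zeta_k + x_ij' eta_k``, so that
  biological effects on feature *scale* (e.g. higher male variance) survive
  harmonization instead of being flattened into a pooled target variance.

Site scale parameters are identified by fitting the scale model with one free
constant per site (no global intercept), then taking the sample-size-weighted
mean of the site constants as zeta_k and the deviations as log(delta_ik), so
sum_i n_i * log(delta_ik) = 0.  The same scheme with an empty covariate list
yields the pooled sigma used by the non-LS methods, which makes ComBatLS with
no scale terms collapse exactly onto ComBat-GAM.

Site parameters (and only those) are stabilized by parametric empirical-Bayes
shrinkage across features within user-specified groups: a normal prior on
gamma and an inverse-gamma prior on delta^2, hyperparameters by method of
moments, solved by iterated conditional posterior means.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import Cohort
from .design import (
    DesignInfo,
    Linear,
    Spline,
    Term,
    build_design,
    penalized_lstsq_gcv,
)

METHODS = ("combat", "combat_nocov", "combat_gam", "combat_ls")


class ConvergenceError(RuntimeError):
    """Iterative fit failed to converge."""


# ---------------------------------------------------------------------------
# model components
# ---------------------------------------------------------------------------

@dataclass
class MeanModelFit:
    """Per-feature intercept, covariate effects, and raw site offsets."""

    alpha: np.ndarray            # (k,)
    beta: np.ndarray             # (p_cov, k)
    design_info: DesignInfo
    gamma_hat: np.ndarray        # (m, k), sum_i n_i gamma = 0
    lam: np.ndarray              # (k,) chosen smoothing parameters
    edf: np.ndarray              # (k,)

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        """Covariate-driven mean alpha_k + f_k(x), excluding site offsets."""
        zcov = self.design_info.transform(covariates)
        return self.alpha + zcov @ self.beta


@dataclass
class ScaleModelFit:
    """Log-linear scale model and site scale factors."""

    zeta: np.ndarray             # (k,) pooled log-scale intercept
    eta: np.ndarray              # (p_scale, k) covariate coefficients
    design_info: DesignInfo
    delta_hat: np.ndarray        # (m, k), sum_i n_i log(delta) = 0
    n_iter: int

    @property
    def pooled_sigma(self) -> np.ndarray:
        """Residual SD used when no scale covariates are modeled."""
        return np.exp(self.zeta)

    def predict_sd(self, covariates: pd.DataFrame) -> np.ndarray:
        """exp(zeta_k + x' eta_k) per subject and feature."""
        wcov = self.design_info.transform(covariates)
        return np.exp(self.zeta + wcov @ self.eta)


def _onehot(batch_idx: np.ndarray, m: int) -> np.ndarray:
    b = np.zeros((len(batch_idx), m))
    b[np.arange(len(batch_idx)), batch_idx] = 1.0
    return b


def fit_mean_model(
    y: np.ndarray,
    covariates: pd.DataFrame,
    mean_terms: list[Term],
    batch_idx: np.ndarray,
    n_i: np.ndarray,
    lam_grid=None,
) -> MeanModelFit:
    """Jointly fit covariate effects and constrained site offsets.

    Solves penalized least squares for each feature with one free constant per
    site and no global intercept; the weighted mean of the site constants is
    the intercept alpha_k and the deviations are gamma_hat with
    ``sum_i n_i gamma_hat = 0`` exactly.  Spline smoothing is chosen by GCV.
    """
    y = np.asarray(y, dtype=float)
    m = len(n_i)
    n = y.shape[0]
    zcov, info = build_design(covariates, mean_terms, include_intercept=False)
    z = np.hstack([_onehot(batch_idx, m), zcov])
    pen = np.zeros((z.shape[1], z.shape[1]))
    pcov = info.penalty()
    if pcov.size:
        pen[m:, m:] = pcov
    if not np.any(pen) and np.linalg.matrix_rank(z) < z.shape[1]:
        raise ValueError("mean-model design is singular (aliased batch/covariates)")
    coefs, lam, edf = penalized_lstsq_gcv(z, y, pen, lam_grid)
    site_coefs = coefs[:m]
    w = n_i / n
    alpha = w @ site_coefs
    gamma_hat = site_coefs - alpha
    return MeanModelFit(alpha, coefs[m:], info, gamma_hat, lam, edf)


def _gamma_irls(
    w: np.ndarray, r2: np.ndarray, tol: float = 1e-10, max_iter: int = 100
) -> np.ndarray:
    """Vectorized Gamma GLM with log link on squared residuals.

    Maximum likelihood for a normal model with log-linear SD has the same
    score equations as a Gamma GLM on the squared residuals; under the log
    link the IRLS working weights are identically 1, so every update is a
    plain least-squares solve shared across features.
    """
    r2 = np.maximum(r2, 1e-300)
    wtw = w.T @ w
    chol = np.linalg.cholesky(wtw)

    def solve(rhs):
        return np.linalg.solve(chol.T, np.linalg.solve(chol, rhs))

    b = solve(w.T @ np.log(r2))
    last_dev = None
    for _ in range(max_iter):
        eta = w @ b
        mu = np.exp(np.clip(eta, -700, 700))
        resp = eta + (r2 - mu) / mu
        b_new = solve(w.T @ resp)
        step = np.max(np.abs(b_new - b))
        b = b_new
        last_dev = float(np.sum(r2 / mu - np.log(r2 / mu) - 1.0))
        if step < tol:
            return b
    raise ConvergenceError(
        f"scale-model IRLS did not converge in {max_iter} iterations "
        f"(last deviance {last_dev:.6g})"
    )


def fit_scale_model(
    resid: np.ndarray,
    covariates: pd.DataFrame,
    scale_terms: list[Term],
    batch_idx: np.ndarray,
    n_i: np.ndarray,
) -> ScaleModelFit:
    """Fit log(SD) = site constant + x' eta on mean-model residuals.

    The model is fit without a global intercept (one free constant per site);
    zeta_k is then the n_i-weighted mean of the site constants and delta_hat
    the exponentiated deviations, giving ``sum_i n_i log(delta_hat) = 0``.
    With no scale terms the site constants have the closed form
    ``0.5 * log(mean_i resid^2)`` and no iteration is needed.
    """
    resid = np.asarray(resid, dtype=float)
    m = len(n_i)
    wcov, info = build_design(covariates, scale_terms, include_intercept=False)
    if wcov.shape[1] == 0:
        sums = _onehot(batch_idx, m).T @ resid**2
        c = 0.5 * np.log(np.maximum(sums / n_i[:, None], 1e-300))
        eta = np.zeros((0, resid.shape[1]))
        n_iter = 0
    else:
        w = np.hstack([_onehot(batch_idx, m), wcov])
        b = _gamma_irls(w, resid**2)
        c = b[:m] / 2.0
        eta = b[m:] / 2.0
        n_iter = 1
    zeta = (n_i / n_i.sum()) @ c
    delta_hat = np.exp(c - zeta)
    return ScaleModelFit(zeta, eta, info, delta_hat, n_iter)


def standardize(
    y: np.ndarray, mean_fit: MeanModelFit, scale_fit: ScaleModelFit,
    covariates: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize observations: z = (y - alpha - f(x)) / exp(zeta + x'eta).

    Returns ``(z, mu_hat, denom)`` so the transform can be inverted exactly
    as ``y = z * denom + mu_hat``.
    """
    mu_hat = mean_fit.predict(covariates)
    denom = scale_fit.predict_sd(covariates)
    return (np.asarray(y, dtype=float) - mu_hat) / denom, mu_hat, denom


def eb_shrink(
    z: np.ndarray,
    batch_idx: np.ndarray,
    n_i: np.ndarray,
    gamma_z: np.ndarray,
    delta_hat: np.ndarray,
    groups: np.ndarray | None = None,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Parametric empirical-Bayes shrinkage of site parameters across features.

    Within each feature group and site, gamma estimates get a normal prior and
    delta^2 estimates an inverse-gamma prior, with method-of-moments
    hyperparameters from the cross-feature spread.  Posterior means are
    iterated until ``max |change| < tol``.  Groups with fewer than two
    features, or with degenerate cross-feature spread, are left unshrunk.
    """
    k = z.shape[1]
    groups = np.zeros(k, dtype=int) if groups is None else np.asarray(groups)
    gamma_star = gamma_z.copy()
    delta2_star = delta_hat.astype(float) ** 2
    m = len(n_i)
    for lev in pd.unique(groups):
        sel = np.flatnonzero(groups == lev)
        if len(sel) < 2:
            warnings.warn(
                f"EB group {lev!r} has fewer than 2 features; shrinkage skipped",
                stacklevel=2,
            )
            continue
        for i in range(m):
            g_hat = gamma_z[i, sel]
            d2 = delta_hat[i, sel] ** 2
            gbar = float(np.mean(g_hat))
            t2 = float(np.var(g_hat, ddof=1))
            d2m = float(np.mean(d2))
            d2s = float(np.var(d2, ddof=1))
            shrink_g = t2 > 1e-12
            shrink_d = d2s > 1e-12 * max(d2m**2, 1e-30)
            if not (shrink_g or shrink_d):
                continue
            zi = z[batch_idx == i][:, sel]
            ni = n_i[i]
            if shrink_d:
                a_prior = (2.0 * d2s + d2m**2) / d2s
                b_prior = (d2m * d2s + d2m**3) / d2s
            g_new, d2_new = g_hat.copy(), d2.copy()
            for it in range(max_iter):
                g_old, d2_old = g_new, d2_new
                if shrink_g:
                    g_new = (ni * t2 * g_hat + d2_new * gbar) / (ni * t2 + d2_new)
                if shrink_d:
                    sum2 = np.sum((zi - g_new) ** 2, axis=0)
                    d2_new = (b_prior + 0.5 * sum2) / (ni / 2.0 + a_prior - 1.0)
                change = max(
                    float(np.max(np.abs(g_new - g_old))),
                    float(np.max(np.abs(d2_new - d2_old))),
                )
                if change < tol:
                    break
            else:
                raise ConvergenceError(
                    f"EB shrinkage did not converge for group {lev!r}, site {i} "
                    f"(last change {change:.3g} after {max_iter} iterations)"
                )
            gamma_star[i, sel] = g_new
            delta2_star[i, sel] = d2_new
    return gamma_star, np.sqrt(delta2_star)


def apply_harmonization(
    z: np.ndarray,
    denom: np.ndarray,
    mu_hat: np.ndarray,
    gamma_star: np.ndarray,
    delta_star: np.ndarray,
    batch_idx: np.ndarray,
) -> np.ndarray:
    """Back-transform: y_h = exp(zeta + x'eta) * (z - gamma*) / delta* + alpha + f(x)."""
    if np.any(delta_star <= 0):
        raise ValueError("delta_star must be strictly positive")
    return denom * (z - gamma_star[batch_idx]) / delta_star[batch_idx] + mu_hat


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class ComBatHarmonizer(TransformerMixin, BaseEstimator):
    """Batch-effect harmonizer in the ComBat family.

    Parameters
    ----------
    method : {"combat", "combat_nocov", "combat_gam", "combat_ls"}
        Covariate model (see module docstring).
    mean_terms, scale_terms : list of design terms or None
        Override the per-method default covariate models.  Scale terms are
        only permitted for ``combat_ls``.  Defaults: linear age + sex
        (``combat``), P-spline age + linear sex (``combat_gam``/``combat_ls``
        mean), linear age + sex (``combat_ls`` scale), none (``combat_nocov``).
    eb : bool
        Apply empirical-Bayes shrinkage to site parameters.
    eb_groups : array-like of shape (n_features,) or None
        Feature-group labels for EB pooling (e.g. schema categories);
        None pools all features together.
    n_knots : int
        Interior knots for default age splines.
    min_batch_size : int
        Batches smaller than this are rejected.

    The estimator is a transformer: ``fit`` learns all site and covariate
    parameters; ``transform`` removes site effects while restoring covariate
    effects on mean (all methods) and scale (``combat_ls``).  ``covariates``
    (a DataFrame) and ``batch`` are passed as keyword arguments to both.
    """

    def __init__(
        self,
        method: str = "combat_ls",
        mean_terms=None,
        scale_terms=None,
        eb: bool = True,
        eb_groups=None,
        n_knots: int = 10,
        lam_grid=None,
        min_batch_size: int = 3,
        eb_tol: float = 1e-4,
        eb_max_iter: int = 500,
    ):
        self.method = method
        self.mean_terms = mean_terms
        self.scale_terms = scale_terms
        self.eb = eb
        self.eb_groups = eb_groups
        self.n_knots = n_knots
        self.lam_grid = lam_grid
        self.min_batch_size = min_batch_size
        self.eb_tol = eb_tol
        self.eb_max_iter = eb_max_iter

    # -- term resolution -------------------------------------------------
    def _resolve_terms(self) -> tuple[list[Term], list[Term]]:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        defaults_mean = {
            "combat": [Linear("age"), Linear("sex")],
            "combat_nocov": [],
            "combat_gam": [Spline("age", n_knots=self.n_knots), Linear("sex")],
            "combat_ls": [Spline("age", n_knots=self.n_knots), Linear("sex")],
        }
        defaults_scale = {
            "combat": [],
            "combat_nocov": [],
            "combat_gam": [],
            "combat_ls": [Linear("age"), Linear("sex")],
        }
        mean_terms = (
            list(self.mean_terms)
            if self.mean_terms is not None
            else defaults_mean[self.method]
        )
        scale_terms = (
            list(self.scale_terms)
            if self.scale_terms is not None
            else defaults_scale[self.method]
        )
        if scale_terms and self.method != "combat_ls":
            raise ValueError("scale_terms are only supported for method='combat_ls'")
        return mean_terms, scale_terms

    @staticmethod
    def _as_cov_df(covariates, n: int) -> pd.DataFrame:
        if covariates is None:
            return pd.DataFrame(index=pd.RangeIndex(n))
        if not isinstance(covariates, pd.DataFrame):
            raise TypeError("covariates must be a pandas DataFrame or None")
        if len(covariates) != n:
            raise ValueError("covariates length does not match number of subjects")
        return covariates.reset_index(drop=True)

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y=None, *, covariates=None, batch=None, feature_names=None):
        if batch is None:
            raise ValueError("batch labels are required")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if not np.all(np.isfinite(X)):
            raise ValueError("feature matrix contains non-finite values")
        n, k = X.shape
        batch = np.asarray(batch)
        if len(batch) != n:
            raise ValueError("batch length does not match number of subjects")
        levels, batch_idx = np.unique(batch, return_inverse=True)
        n_i = np.bincount(batch_idx).astype(float)
        if n_i.min() < self.min_batch_size:
            small = {str(levels[i]): int(n_i[i]) for i in np.flatnonzero(
                n_i < self.min_batch_size)}
            raise ValueError(
                f"every batch needs at least {self.min_batch_size} subjects; "
                f"too small: {small}"
            )
        if len(levels) == 1:
            warnings.warn(
                "only one batch present; harmonization is the identity",
                stacklevel=2,
            )
        mean_terms, scale_terms = self._resolve_terms()
        cov_df = self._as_cov_df(covariates, n)

        mean_fit = fit_mean_model(X, cov_df, mean_terms, batch_idx, n_i,
                                  self.lam_grid)
        mu_hat = mean_fit.predict(cov_df)
        resid = X - mu_hat - mean_fit.gamma_hat[batch_idx]
        scale_fit = fit_scale_model(resid, cov_df, scale_terms, batch_idx, n_i)
        z, mu_hat, denom = standardize(X, mean_fit, scale_fit, cov_df)

        # site offsets on the standardized scale, constrained to weighted sum 0
        site_mean_z = _onehot(batch_idx, len(levels)).T @ z / n_i[:, None]
        gamma_z = site_mean_z - (n_i / n) @ site_mean_z

        groups = None
        if self.eb_groups is not None:
            groups = np.asarray(self.eb_groups)
            if len(groups) != k:
                raise ValueError("eb_groups length must equal number of features")
        if self.eb:
            gamma_star, delta_star = eb_shrink(
                z, batch_idx, n_i, gamma_z, scale_fit.delta_hat, groups,
                tol=self.eb_tol, max_iter=self.eb_max_iter,
            )
        else:
            gamma_star, delta_star = gamma_z.copy(), scale_fit.delta_hat.copy()

        self.feature_names_ = (
            list(feature_names) if feature_names is not None
            else [f"feature_{j}" for j in range(k)]
        )
        self.batch_levels_ = levels
        self.n_per_batch_ = n_i
        self.mean_fit_ = mean_fit
        self.scale_fit_ = scale_fit
        self.alpha_ = mean_fit.alpha
        self.gamma_hat_ = mean_fit.gamma_hat
        self.zeta_ = scale_fit.zeta
        self.eta_ = scale_fit.eta
        self.delta_hat_ = scale_fit.delta_hat
        self.pooled_sigma_ = scale_fit.pooled_sigma
        self.gamma_z_ = gamma_z
        self.gamma_star_ = gamma_star
        self.delta_star_ = delta_star
        self.eb_groups_ = groups
        return self

    # -- application -------------------------------------------------------
    def transform(self, X, *, covariates=None, batch=None):
        if not hasattr(self, "gamma_star_"):
            raise RuntimeError("ComBatHarmonizer is not fitted")
        if batch is None:
            raise ValueError("batch labels are required")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = X.shape[0]
        batch = np.asarray(batch)
        lookup = {lev: i for i, lev in enumerate(self.batch_levels_)}
        try:
            batch_idx = np.array([lookup[b] for b in batch])
        except KeyError as exc:
            raise ValueError(f"unseen batch level: {exc.args[0]!r}") from None
        cov_df = self._as_cov_df(covariates, n)
        z, mu_hat, denom = standardize(X, self.mean_fit_, self.scale_fit_, cov_df)
        return apply_harmonization(
            z, denom, mu_hat, self.gamma_star_, self.delta_star_, batch_idx
        )

    def fit_transform(self, X, y=None, **fit_params):
        self.fit(X, y, **fit_params)
        return self.transform(
            X,
            covariates=fit_params.get("covariates"),
            batch=fit_params.get("batch"),
        )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        arr = lambda a: np.asarray(a).tolist()
        return {
            "params": {
                "method": self.method,
                "eb": self.eb,
                "n_knots": self.n_knots,
                "min_batch_size": self.min_batch_size,
            },
            "batch_levels": arr(self.batch_levels_),
            "n_per_batch": arr(self.n_per_batch_),
            "feature_names": self.feature_names_,
            "alpha": arr(self.alpha_),
            "beta": arr(self.mean_fit_.beta),
            "mean_design": self.mean_fit_.design_info.to_dict(),
            "lam": arr(self.mean_fit_.lam),
            "gamma_hat": arr(self.gamma_hat_),
            "zeta": arr(self.zeta_),
            "eta": arr(self.eta_),
            "scale_design": self.scale_fit_.design_info.to_dict(),
            "delta_hat": arr(self.delta_hat_),
            "gamma_star": arr(self.gamma_star_),
            "delta_star": arr(self.delta_star_),
            "eb_groups": arr(self.eb_groups_) if self.eb_groups_ is not None else None,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "ComBatHarmonizer":
        est = cls(**d["params"])
        est.batch_levels_ = np.asarray(d["batch_levels"])
        est.n_per_batch_ = np.asarray(d["n_per_batch"], dtype=float)
        est.feature_names_ = d["feature_names"]
        mean_info = DesignInfo.from_dict(d["mean_design"])
        scale_info = DesignInfo.from_dict(d["scale_design"])
        est.alpha_ = np.asarray(d["alpha"])
        est.gamma_hat_ = np.asarray(d["gamma_hat"])
        est.mean_fit_ = MeanModelFit(
            est.alpha_, np.asarray(d["beta"]), mean_info, est.gamma_hat_,
            np.asarray(d["lam"]), np.zeros(len(d["alpha"])),
        )
        est.zeta_ = np.asarray(d["zeta"])
        est.eta_ = np.asarray(d["eta"])
        est.delta_hat_ = np.asarray(d["delta_hat"])
        est.scale_fit_ = ScaleModelFit(
            est.zeta_, est.eta_, scale_info, est.delta_hat_, 0
        )
        est.pooled_sigma_ = est.scale_fit_.pooled_sigma
        est.gamma_star_ = np.asarray(d["gamma_star"])
        est.delta_star_ = np.asarray(d["delta_star"])
        est.gamma_z_ = est.gamma_star_.copy()
        est.eb_groups_ = (
            np.asarray(d["eb_groups"]) if d["eb_groups"] is not None else None
        )
        return est

    @classmethod
    def load(cls, path) -> "ComBatHarmonizer":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def harmonize(
    cohort: Cohort,
    method: str = "combat_ls",
    mean_terms=None,
    scale_terms=None,
    eb: bool = True,
    eb_groups=None,
    schema=None,
    **kwargs,
) -> tuple[Cohort, ComBatHarmonizer]:
    """Harmonize a cohort end to end; returns the harmonized cohort and the fit.

    ``eb_groups`` may be an explicit label array or the string ``"schema"`` to
    pool EB estimates within the categories of ``schema`` (global / volume /
    area / thickness), as is standard for neuroanatomical feature sets.
    """
    cohort.validate(min_batch_size=kwargs.get("min_batch_size", 3))
    if isinstance(eb_groups, str):
        if eb_groups != "schema":
            raise ValueError("eb_groups string form must be 'schema'")
        if schema is None:
            raise ValueError("eb_groups='schema' requires a FeatureSchema")
        eb_groups = schema.categories(cohort.feature_names)
    est = ComBatHarmonizer(
        method=method,
        mean_terms=mean_terms,
        scale_terms=scale_terms,
        eb=eb,
        eb_groups=eb_groups,
        **kwargs,
    )
    harmonized = est.fit_transform(
        cohort.features.to_numpy(dtype=float),
        covariates=cohort.covariates,
        batch=cohort.batch.to_numpy(),
        feature_names=cohort.feature_names,
    )
    out = Cohort(
        features=pd.DataFrame(
            harmonized, index=cohort.features.index, columns=cohort.features.columns
        ),
        covariates=cohort.covariates.copy(),
        log_scale=cohort.log_scale,
        n_dropped=cohort.n_dropped,
    )
    return out, est
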