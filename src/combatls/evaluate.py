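"""Harmonization quality metrics: centile errors, rank-based tests, sex-bias
summaries, extreme-centile representation, and residual site-effect sizes.

Centile error is the harmonized-data centile minus the ground-truth centile
for the same subject and feature; negative values mean harmonization
underestimated the subject's standing.  Because paired centile-error
magnitudes are skewed and heteroskedastic, between-method and between-sex
comparisons convert the pooled values to midranks before a two-tailed Welch
t-test on the rank vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bccg import bccg_mean_var
from .design import Categorical
from .normative import BCCGNormativeModel, NormativeSpec, fit_normative


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    comparison: str = ""
    p_fdr: float | None = None


@dataclass
class CentileErrorTable:
    """Signed and absolute per-subject, per-feature centile errors."""

    signed: np.ndarray
    feature_names: list[str] | None = None

    @property
    def absolute(self) -> np.ndarray:
        return np.abs(self.signed)


def centile_errors(
    harmonized_centiles, true_centiles, feature_names=None
) -> CentileErrorTable:
    """Harmonized-data centile minus ground-truth centile, elementwise."""
    h = np.asarray(harmonized_centiles, dtype=float)
    t = np.asarray(true_centiles, dtype=float)
    if h.shape != t.shape:
        raise ValueError(
            f"centile grids are misaligned: {h.shape} vs {t.shape}"
        )
    return CentileErrorTable(h - t, feature_names)


def rank_welch_test(
    a, b, paired_on_differences: bool = False, comparison: str = ""
) -> TestResult:
    """Two-tailed t-test with Welch's correction on pooled midranks.

    ``a`` and ``b`` are paired samples of equal length; ties receive average
    ranks over the pooled concatenation.  With ``paired_on_differences`` the
    alternative one-sample t-test on within-subject rank differences is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-d paired samples of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    ranks = stats.rankdata(np.concatenate([a, b]))
    ra, rb = ranks[:n], ranks[n:]
    va = np.var(ra, ddof=1)
    vb = np.var(rb, ddof=1)
    if paired_on_differences:
        d = ra - rb
        sd = np.std(d, ddof=1)
        if sd == 0:
            if np.all(d == 0):
                return TestResult(0.0, float(n - 1), 1.0, comparison)
            raise ValueError("degenerate rank differences")
        t = float(np.mean(d) / (sd / np.sqrt(n)))
        df = float(n - 1)
    else:
        if va == 0 and vb == 0:
            raise ValueError("both rank vectors are constant; statistic undefined")
        sa, sb = va / n, vb / n
        se = np.sqrt(sa + sb)
        t = float((np.mean(ra) - np.mean(rb)) / se)
        df = float(
            (sa + sb) ** 2 / (sa**2 / (n - 1) + sb**2 / (n - 1))
        )
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TestResult(t, df, p, comparison)


def bh_fdr(pvals, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg (or, with ``method='by'``, Benjamini-Yekutieli)
    step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    key = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    return multipletests(p.ravel(), method=key)[1].reshape(p.shape)


# ---------------------------------------------------------------------------
# sex bias
# ---------------------------------------------------------------------------

@dataclass
class SexBiasReport:
    per_feature: pd.Series          # median male error - median female error
    per_category: pd.Series         # median of member features per category


def sex_bias_metrics(
    errors, sex, categories=None, feature_names=None
) -> SexBiasReport:
    """Directional sex differences in signed centile errors.

    Per feature: median error among males minus median among females.
    Per category: the median of its member features' differences.
    """
    e = np.atleast_2d(np.asarray(errors, dtype=float))
    sex = np.asarray(sex, dtype=int)
    if len(np.unique(sex)) < 2:
        raise ValueError("both sexes must be present")
    male = sex == 1
    diff = np.median(e[male], axis=0) - np.median(e[~male], axis=0)
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"feature_{j}" for j in range(e.shape[1])]
    )
    per_feature = pd.Series(diff, index=names)
    if categories is None:
        per_category = pd.Series({"all": float(np.median(diff))})
    else:
        cats = np.asarray(categories)
        per_category = pd.Series(
            {c: float(np.median(diff[cats == c])) for c in pd.unique(cats)}
        )
    return SexBiasReport(per_feature, per_category)


def one_sample_bias_tests(replication_table: pd.DataFrame) -> pd.DataFrame:
    """Two-sided one-sample t-tests of per-replication bias metrics against 0,
    FDR-corrected across all columns (method x category cells)."""
    rows = []
    for col in replication_table.columns:
        x = replication_table[col].to_numpy(dtype=float)
        res = stats.ttest_1samp(x, 0.0)
        rows.append(
            {"cell": col, "mean": float(np.mean(x)),
             "statistic": float(res.statistic), "p_value": float(res.pvalue)}
        )
    out = pd.DataFrame(rows).set_index("cell")
    out["p_fdr"] = bh_fdr(out["p_value"].to_numpy())
    return out


def extreme_centile_bias(
    method_mean_centiles,
    truth_mean_centiles,
    sex,
    category_names=None,
    low: float = 0.2,
    high: float = 0.8,
) -> pd.DataFrame:
    """Female over/under-representation among extreme average centiles.

    Inputs are per-subject average centiles within feature categories
    (columns).  For each category and tail ("low" < ``low``, "high" >
    ``high``), the female proportion under the method minus the truth-derived
    expected proportion.  Empty extreme groups yield NaN with a flag.
    """
    m = np.atleast_2d(np.asarray(method_mean_centiles, dtype=float))
    t = np.atleast_2d(np.asarray(truth_mean_centiles, dtype=float))
    if m.shape != t.shape:
        raise ValueError("method and truth centile grids are misaligned")
    sex = np.asarray(sex, dtype=int)
    female = sex == 0
    cats = (
        list(category_names)
        if category_names is not None
        else [f"category_{j}" for j in range(m.shape[1])]
    )
    rows = []
    for j, cat in enumerate(cats):
        for tail, sel_m, sel_t in (
            ("low", m[:, j] < low, t[:, j] < low),
            ("high", m[:, j] > high, t[:, j] > high),
        ):
            def prop(sel):
                return float(np.mean(female[sel])) if sel.any() else np.nan
            pm, pt = prop(sel_m), prop(sel_t)
            rows.append(
                {
                    "category": cat,
                    "tail": tail,
                    "female_prop": pm,
                    "expected_prop": pt,
                    "bias": pm - pt,
                    "empty": not (sel_m.any() and sel_t.any()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scale effects and residual site effects
# ---------------------------------------------------------------------------

def scale_sex_effect(
    fit: BCCGNormativeModel,
    ref_covariates: dict,
    y=None,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Standardized sex effect on predicted variance at reference covariates.

    Computes (Var_male - Var_female) / Var_female with both sexes evaluated at
    ``ref_covariates`` (e.g. the sample mean age).  Variances use the BCCG
    second-order form (mu * sigma)^2, exact at nu = 1.  If the training data
    are supplied, significance of the sigma sex term is assessed by a
    likelihood-ratio test against the sigma model with that term dropped.
    """
    ref = {k: [v, v] for k, v in ref_covariates.items()}
    ref["sex"] = [0, 1]
    grid = pd.DataFrame(ref)
    mu, sigma, nu = fit.predict_params(grid)
    _, var = bccg_mean_var(mu, sigma, nu)
    var_f, var_m = float(var[0]), float(var[1])
    out = {"effect": (var_m - var_f) / var_f, "var_female": var_f,
           "var_male": var_m}
    if y is not None and covariates is not None:
        reduced_terms = [
            t for t in fit._spec().sigma_terms
            if getattr(t, "name", None) != "sex"
        ]
        reduced = BCCGNormativeModel(
            mu_terms=fit._spec().mu_terms,
            sigma_terms=reduced_terms,
            nu_terms=fit._spec().nu_terms,
            smooth_lambda=fit.smooth_lambda,
            max_iter=fit.max_iter,
        ).fit(covariates, y)
        lr = 2.0 * (fit.loglik_ - reduced.loglik_)
        p = float(stats.chi2.sf(max(lr, 0.0), df=1))
        out.update({"lr_statistic": lr, "p_value": p, "significant": p < 0.05})
    return out


def generalized_r2(ll_model: float, ll_null: float, n: int) -> float:
    """Cox-Snell style generalized R^2 = 1 - (L0/L1)^(2/n)."""
    return 1.0 - float(np.exp((2.0 / n) * (ll_null - ll_model)))


def residual_site_f2(
    y,
    covariates: pd.DataFrame,
    batch,
    spec: NormativeSpec | None = None,
    **fit_kwargs,
) -> dict:
    """Cohen's f^2 for the residual batch term in a normative model.

    Fits the BCCG model with and without fixed batch effects in the mu and
    sigma predictors; pseudo-R^2 values are computed against a common
    intercept-only null, and f^2 = (R2_full - R2_reduced) / (1 - R2_full).
    """
    batch = np.asarray(batch)
    if len(np.unique(batch)) < 2:
        raise ValueError("need at least 2 batches")
    spec = spec or NormativeSpec()
    cov = covariates.reset_index(drop=True).copy()
    cov["batch"] = batch
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)

    null_fit = fit_normative(
        y, cov, NormativeSpec(mu_terms=[], sigma_terms=[], nu_terms=[]),
        **fit_kwargs,
    )
    reduced = fit_normative(y, cov, spec, **fit_kwargs)
    full_spec = NormativeSpec(
        mu_terms=list(spec.mu_terms) + [Categorical("batch")],
        sigma_terms=list(spec.sigma_terms) + [Categorical("batch")],
        nu_terms=list(spec.nu_terms),
    )
    full = fit_normative(y, cov, full_spec, **fit_kwargs)

    flagged = not (null_fit.converged_ and reduced.converged_ and full.converged_)
    if flagged:
        warnings.warn("a site-effect fit did not converge; entry flagged",
                      stacklevel=2)
    r2_red = generalized_r2(reduced.loglik_, null_fit.loglik_, n)
    r2_full = generalized_r2(full.loglik_, null_fit.loglik_, n)
    f2 = max(r2_full - r2_red, 0.0) / max(1.0 - r2_full, 1e-12)
    return {
        "r2_full": r2_full,
        "r2_reduced": r2_red,
        "f2": f2,
        "converged": not flagged,
    }


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def method_comparison_report(
    abs_errors: dict[str, np.ndarray],
    feature_names=None,
    categories=None,
    alpha: float = 0.05,
) -> dict:
    """Pairwise rank-Welch comparisons of absolute centile errors per feature,
    FDR over (pairings x features), plus per-category medians and win counts.

    ``abs_errors`` maps method name -> (subjects x features) absolute errors.
    A method "wins" a feature when its median absolute error is the smallest.
    """
    methods = list(abs_errors)
    if len(methods) < 2:
        raise ValueError("need at least 2 methods to compare")
    mats = {m: np.atleast_2d(np.asarray(v, float)) for m, v in abs_errors.items()}
    k = next(iter(mats.values())).shape[1]
    names = (
        list(feature_names) if feature_names is not None
        else [f"feature_{j}" for j in range(k)]
    )
    rows = []
    for i, ma in enumerate(methods):
        for mb in methods[i + 1:]:
            for j in range(k):
                res = rank_welch_test(
                    mats[ma][:, j], mats[mb][:, j],
                    comparison=f"{ma} vs {mb} | {names[j]}",
                )
                rows.append(
                    {"method_a": ma, "method_b": mb, "feature": names[j],
                     "statistic": res.statistic, "df": res.df,
                     "p_value": res.p_value}
                )
    tests = pd.DataFrame(rows)
    tests["p_fdr"] = bh_fdr(tests["p_value"].to_numpy())
    tests["significant"] = tests["p_fdr"] < alpha

    med = pd.DataFrame(
        {m: np.median(mats[m], axis=0) for m in methods}, index=names
    )
    wins = med.idxmin(axis=1).value_counts().reindex(methods, fill_value=0)
    if categories is not None:
        cats = np.asarray(categories)
        cat_median = pd.DataFrame(
            {m: {c: float(np.median(med[m].to_numpy()[cats == c]))
                 for c in pd.unique(cats)} for m in methods}
        )
    else:
        cat_median = med.median().to_frame().T.rename(index={0: "all"})
    return {
        "tests": tests,
        "median_abs_error": med,
        "category_median": cat_median,
        "wins": wins,
    }
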