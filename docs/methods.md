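# Methods

## The problem

Pooling measurements collected at multiple sites or scanners introduces batch
effects: additive offsets and multiplicative rescalings of each feature that
have nothing to do with biology. The ComBat family removes these while
preserving the effects of declared biological covariates. Classic ComBat and
ComBat-GAM preserve covariate effects on feature *means* only; both force
every site toward a single pooled residual variance. When a covariate also
drives the residual *scale* — males' neuroanatomical volumes, for instance,
are more variable than females' — and the covariate is unevenly distributed
across sites, this pooling erases real biological dispersion and distorts any
downstream quantity that depends on it, most visibly normative centile and
Z-scores.

`combatls` implements the location- *and* scale-preserving extension
(ComBatLS) alongside linear ComBat, ComBat-GAM, and a no-covariate ComBat
lower bound, plus everything needed to quantify the damage each method does
to normative scores on synthetic cohorts with known ground truth.

## Harmonization model

For site *i*, subject *j*, feature *k*:

    y_ijk = alpha_k + f_k(x_ij) + gamma_ik + delta_ik * e_ijk

* `alpha_k` — feature intercept; `f_k` — covariate effect on the mean
  (linear terms, or a cubic P-spline for age);
* `gamma_ik`, `delta_ik` — additive and multiplicative site effects,
  identified by `sum_i n_i gamma_ik = 0` and `sum_i n_i log delta_ik = 0`;
* `e_ijk` — mean-zero noise. For ComBatLS the noise SD is itself modeled
  log-linearly in covariates: `log sigma_ijk = zeta_k + x_ij' eta_k`;
  the other methods use a single pooled `sigma_k`.

Fitting proceeds in the usual ComBat stages:

1. **Mean model.** Penalized least squares per feature with one free
   constant per site and no global intercept; `alpha_k` is the
   sample-size-weighted mean of the site constants and `gamma_hat` the
   deviations, which makes the gamma constraint exact. Spline smoothing is
   selected by GCV on a shared log-spaced grid; all features share the basis,
   so the expensive linear algebra is done once per grid point.
2. **Scale model.** Maximum likelihood for the normal model with log-linear
   SD has the same score equations as a Gamma GLM with log link on the
   squared residuals, and under the log link the IRLS working weights are
   identically one — so the fit is a plain iterated least-squares solve,
   vectorized across features (one Cholesky of the design Gram matrix,
   reused). The model is fit with one free constant per site and no global
   intercept; `zeta_k` is the weighted mean of the site constants and
   `delta_hat_ik` the exponentiated deviations, making the log-delta
   constraint exact. With no scale covariates the site constants collapse to
   the closed form `0.5 * log(mean residual^2)` per site.
3. **Standardization.** `z = (y - alpha - f(x)) / exp(zeta + x'eta)`.
   Site offsets on the standardized scale are re-estimated as constrained
   within-site means of `z` (weighted sum zero), which makes single-batch
   harmonization an exact identity.
4. **Empirical Bayes.** Within user-chosen feature groups (by default the
   schema categories global / volume / area / thickness), per-site gamma
   estimates receive a normal prior and delta^2 estimates an inverse-gamma
   prior across features, hyperparameters by method of moments, solved by
   iterated conditional posterior means to an absolute tolerance of 1e-4
   (cap 500 iterations, error on failure). Degenerate cross-feature spread
   (all estimates equal) is a fixed point and is left unshrunk; only site
   parameters are ever shrunk — `eta` and `zeta` are not.
5. **Back-transform.**
   `y_harmonized = exp(zeta + x'eta) * (z - gamma*) / delta* + alpha + f(x)`.

### Design choices worth knowing about

* **Pooled sigma is geometric, not arithmetic.** The non-LS methods reuse
  the same identifiability scheme with an empty scale-covariate list, so
  their pooled SD is `exp(zeta_k)` — the n-weighted *geometric* mean of
  per-site ML SDs rather than the arithmetic pooled variance some ComBat
  implementations use. This makes ComBatLS with no scale terms collapse
  exactly onto ComBat-GAM (one code path) and changes nothing else of
  substance; the difference between the two poolings is second-order in the
  spread of site variances.
* **One spline family.** Both the GAM-style and LS-style mean smooths use
  cubic B-splines with a second-order difference penalty (P-splines, 10
  interior knots by default) instead of mixing thin-plate and P-spline
  bases; in one dimension the flexibility is equivalent and the basis is
  cheap, reproducible, and serializable.
* **Minimum batch size 3**; smaller batches raise rather than silently pool.
* All fits are deterministic — there is no stochastic optimizer anywhere,
  so identical inputs give bit-identical fits.

## Normative modeling (BCCG)

Centile scoring uses the Box-Cox Cole-Green (LMS) family: `y > 0` with
`z = ((y/mu)^nu - 1)/(nu*sigma)` standard normal (`log(y/mu)/sigma` at
`nu = 0`). `mu` is the median, `sigma` the approximate coefficient of
variation, `nu` the skewness power. The truncation mass below zero that the
untruncated definition ignores is conventionally neglected;
`bccg.truncation_mass` quantifies it (it is < 1e-4 everywhere we fit).

Each distribution parameter gets its own covariate model with standard
links — log for `mu` and `sigma`, identity for `nu` — and an always-present
intercept. The adult-cohort default is a cubic age polynomial plus linear
sex for `mu` and `log sigma` and a constant `nu`. Although the mean model
could be written with an identity link, positivity of harmonized volumes
demands the log link; at the effect sizes involved the two parameterizations
are practically indistinguishable. Polynomial terms standardize the
covariate internally (training mean/SD) for conditioning, so their
coefficients refer to the standardized variable; `Linear` terms are raw.

Fitting maximizes the (optionally spline-penalized) log-likelihood jointly
over all three coefficient blocks with L-BFGS-B and an analytic gradient,
initialized from a log-scale least-squares fit (`nu` starts at 1).
Joint quasi-Newton was chosen over the block-cyclic scoring used by classic
GAMLSS software: with the closed-form gradient it is simpler, fast at these
model sizes, and inherits a well-tested optimizer. Non-convergence (optimizer
failure with a non-trivial gradient) flags the fit; flagged fits refuse to
score rather than returning silently. Constant responses are rejected up
front as degenerate.

Scoring: `centile = Phi(z)`, `zscore = Phi^{-1}(centile)`; quantile curves
invert the CDF in closed form. Centiles and Z-scores are monotone images of
each other, so analyses run on either rank subjects identically.

## Synthetic cohorts — what they emulate

The generator mimics an adult population-imaging sample and defines the
study conditions used throughout the tests:

* ages uniform on 50–80 years (stored in days), 49.7% female;
* volume-like features: female mean `base_k = 10^4 (k+1)` at the reference
  age 65 y, a mild cubic age decline (−0.4%/y linear term), an 8% male mean
  offset, residual SD 7% of `base` (log-normal scale model), and a sex
  effect on log residual SD of `log 1.5` — males 1.5× more variable, the
  magnitude used in all scale-preservation checks. The null-scale variant
  (`eta_sex = 0`) emulates cortical-thickness-like features whose dispersion
  is sex-insensitive;
* noise is Gaussian by default (BCCG with chosen `nu` available), so every
  subject's true centile is available in closed form from the generating
  parameters — no refit, hence no estimation noise in the ground truth. An
  empirical-truth route (refit normative models on the unharmonized data)
  is available through the same scoring pipeline if wanted.

Site designs: (a) three sites with sex-dependent assignment probabilities —
females 33%/58.75%/8.25%, males 33%/8.25%/58.75% — giving one balanced and
two heavily imbalanced sites of similar size (note the realized within-site
ratios are more extreme than 4:1 given near-equal base rates; the generator
reports realized compositions rather than a nominal label); (b) a two-site
sweep, one site balanced, the second site's male count stepping from 0 to
its full size in 10% increments (11 designs at size 9,400), sampled without
replacement within sex.

Site effects are injected *after* generation: additive shifts in units of
each feature's mean residual SD and multiplicative noise scalings. The main
sex-imbalance experiments inject none — the point is that mean-only
harmonization damages scores even with no true batch differences, purely by
forcing sites with different sex compositions toward a common variance.

What the generator does **not** emulate: inter-regional covariance,
measurement floor/ceiling effects, site-by-covariate interactions, non-random
site membership, longitudinal structure. Passing tests therefore demonstrate
correctness of the machinery and the direction/magnitude of harmonization
effects under these idealized conditions, not performance on any real
cohort.

## Evaluation

* **Centile error** = harmonized-data centile − true centile (negative =
  underestimation); method comparisons use absolute errors.
* **Rank-Welch test**: pooled midranks (average ranks at ties) followed by a
  two-tailed Welch t-test on the two rank vectors — appropriate for paired,
  skewed, variance-unequal error magnitudes, and invariant to monotone
  transforms of the pooled values. (The alternative one-sample t on
  within-subject rank differences is available via
  `paired_on_differences=True` for sensitivity analyses.) Type-I error is
  calibrated to ~5% at nominal alpha = 0.05.
* **FDR**: Benjamini–Hochberg by default, Benjamini–Yekutieli by flag.
* **Sex bias**: per-feature median(male error) − median(female error),
  medians of those within feature categories, one-sample t-tests of the
  across-replication distributions against zero (FDR over method × category
  cells); plus female representation among subjects with extreme (<20% or
  >80%) category-average centiles relative to the truth-derived expectation.
* **Residual site effect**: refit the normative model with and without fixed
  batch effects in the `mu` and `sigma` predictors; pseudo-R² of each model
  against a common intercept-only null via `1 - (L0/L1)^(2/n)`, and
  Cohen's `f² = (R²_full − R²_reduced)/(1 − R²_full)` for the batch term.
* **Scale sex effect**: `(Var_M − Var_F)/Var_F` at reference covariates,
  with variance from the second-order BCCG form `(mu*sigma)²` (exact at
  `nu = 1`); significance by likelihood ratio against the sigma model with
  the sex term dropped.

## Problem sizes

The validation battery runs at desk scale, chosen so the whole suite
completes in well under an hour on one CPU while keeping every Monte-Carlo
margin comfortable: identity/nesting checks at n = 500–600; scale-ratio
recovery at n = 5,000 × 20 seeds; the three-site centile-error ordering at
n = 2,000, 8 features × 20 seeds; site-effect removal at n = 2,000/site ×
3 sites; rank-test calibration at 2,000 null replications of n = 100; BCCG
recovery at n = 5,000 × 20 seeds. The sweep-design count check uses the
full-scale 9,400-per-site design (counting is cheap; only the harmonization
experiments are scaled down).

## Known limitations

* Harmonization of higher moments (skew, kurtosis) is out of scope: site
  effects beyond location and scale pass through.
* EB shrinkage assumes features within a group share exchangeable site
  effects; grossly heterogeneous groups weaken it (use finer `eb_groups`).
* The BCCG engine fits fixed spline penalties (no automatic smoothing
  selection across distribution parameters) and only the BCCG family — no
  BCT/BCPE.
* `transform` on new data requires batches seen at fit time (no
  reference-batch or out-of-sample-site mode) and clips spline covariates to
  the training range with a warning.
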