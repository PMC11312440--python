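# combatls

Batch-effect harmonization for multi-site tabular features (neuroimaging
morphometry and beyond) that preserves covariate effects on both the
**location** and the **scale** of every feature, together with a Box-Cox
Cole-Green (BCCG) normative-modeling engine for centile/Z-scores and a
simulation/evaluation framework that quantifies the centile error and sex
bias each harmonization method induces.

## Who this is for

Anyone pooling continuous features across sites, scanners, or studies and
then computing normative scores (growth-chart centiles, Z-scores, brain-age
style deviations). Classic ComBat-style harmonization preserves covariate
effects on feature *means* but forces all sites toward one pooled residual
variance. If a covariate also affects residual *scale* — male neuroanatomical
volumes are roughly 1.5× as variable as female ones — and sites differ in
their covariate mix, mean-only harmonization silently flattens that
biological dispersion and biases every score computed downstream.

## The model

For site *i*, subject *j*, feature *k*, with covariates `x` (age, sex, ...):

    y_ijk = alpha_k + f_k(x_ij) + gamma_ik + delta_ik * e_ijk

with site constraints `sum_i n_i gamma_ik = 0`, `sum_i n_i log delta_ik = 0`.
The methods differ in the covariate model:

| method         | mean model `f_k`            | scale model                        |
|----------------|-----------------------------|------------------------------------|
| `combat_nocov` | none                        | pooled `sigma_k`                   |
| `combat`       | linear age + sex            | pooled `sigma_k`                   |
| `combat_gam`   | P-spline age + sex          | pooled `sigma_k`                   |
| `combat_ls`    | P-spline age + sex          | `log sigma_ijk = zeta_k + x' eta_k` |

Harmonization standardizes `z = (y - alpha - f(x)) / exp(zeta + x'eta)`,
shrinks the site parameters with parametric empirical Bayes (normal prior on
`gamma`, inverse-gamma on `delta²`, pooled within feature categories), and
back-transforms

    y_harmonized = exp(zeta + x'eta) * (z - gamma*) / delta* + alpha + f(x)

so site offsets and scalings are removed while covariate effects on mean and
(for `combat_ls`) scale are restored. Normative scoring fits
BCCG(mu, sigma, nu) charts — `mu`, `sigma`, `nu` each regressed on
covariates — and reports `centile = Phi(z)` per subject. See
`docs/methods.md` for the estimation details and design choices.

## Worked example

Three synthetic "sites" with heavily sex-imbalanced membership are carved
out of one coherent cohort — there is **no true batch effect** — and then
harmonized. Any centile error is damage done by harmonization itself:

```python
import numpy as np
from combatls import (assign_sites_weighted, default_config, generate_cohort,
                      harmonize, with_batch)
from combatls.experiment import score_cohort

cohort, truth = generate_cohort(default_config(2000, n_features=4), seed=7)
labels = assign_sites_weighted(truth.sex, seed=8)   # three sex-imbalanced sites
cohort = with_batch(cohort, labels)

true_cent = truth.centiles()                        # analytic ground truth
for method in ("combat_gam", "combat_ls"):
    harmonized, fit = harmonize(cohort, method=method)
    cent, _ = score_cohort(harmonized)              # refit brain charts, score
    mae = np.abs(cent - true_cent).mean()
    print(f"{method:11s} mean |centile error| = {mae:.4f}   "
          f"delta_hat site range = {fit.delta_hat_.min():.3f}-{fit.delta_hat_.max():.3f}")
```

```
combat_gam  mean |centile error| = 0.0182   delta_hat site range = 0.849-1.206
combat_ls   mean |centile error| = 0.0115   delta_hat site range = 0.958-1.023
```

Read: the mean-only method misattributes the sites' sex-composition
differences in variance to site scale effects (`delta` spanning 0.85–1.21
despite no true batch effect) and rescales them away, displacing subjects'
centiles by 1.8 points on average. The scale-preserving fit models the sex
effect explicitly, leaves `delta` near 1, and roughly halves the error —
what remains is normative-model estimation noise.

The same estimators compose with scikit-learn conventions
(`ComBatHarmonizer` is a transformer; `BCCGNormativeModel` a fit/predict
estimator with `get_params`/`set_params`), and a `combatls` CLI exposes
`simulate`, `harmonize`, `normative-fit`, `score`, `evaluate`, and
`replicate-experiment` for file-based workflows:

```bash
combatls simulate --n-subjects 2000 --seed 1 --out sim/
combatls harmonize --input sim/cohort.tsv --method combat-ls --out harm/
```

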