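"""Synthetic cohorts with known covariate effects on location and scale.

The generator emulates an adult population-imaging sample: ages uniform on
50-80 years (stored in days), binary sex with a 49.7% female base rate,
volume-like features whose means vary polynomially with age and linearly with
sex, and whose residual SDs follow a log-linear model

    log s(x) = zeta + eta_sex * sex + eta_age * (age_years - 65)

so that e.g. ``eta_sex = log(1.5)`` gives males 1.5x the female residual SD.
Site effects are injected separately (additive shifts in units of a feature's
typical SD, multiplicative scalings of the noise), so the site-free values
and every generating parameter are retained as ground truth, and each
subject's *true centile* under the generating distribution is available in
closed form — no refit required.

Two site-assignment designs are provided: a three-site scheme where the
assignment probability depends on sex (females 33% / 58.75% / 8.25%, males
33% / 8.25% / 58.75%, yielding one balanced and two heavily sex-imbalanced
sites), and a two-site sweep where one site stays balanced while the second
site's male count runs from 0% to 100% of its sample in fixed steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .bccg import bccg_cdf, bccg_quantile
from .cohort import Cohort

DAYS_PER_YEAR = 365.25
REF_AGE_YEARS = 65.0

#: per-sex site-assignment probabilities (rows: female, male)
DEFAULT_THREE_SITE_PROBS = np.array(
    [[0.33, 0.5875, 0.0825],
     [0.33, 0.0825, 0.5875]]
)


@dataclass(frozen=True)
class FeatureGen:
    """Generating parameters for one feature.

    ``base`` is the female mean at the reference age (65 y); ``age1..age3``
    multiply powers of (age_years - 65); ``zeta`` is the log residual SD at
    the reference covariates.  ``noise`` is "normal" or "bccg" (with power
    ``nu`` and sigma = SD / mean).
    """

    name: str
    base: float
    age1: float = 0.0
    age2: float = 0.0
    age3: float = 0.0
    sex_effect: float = 0.0
    zeta: float = 0.0
    eta_sex: float = 0.0
    eta_age: float = 0.0
    noise: str = "normal"
    nu: float = 1.0


@dataclass
class GeneratorConfig:
    n_subjects: int
    features: list[FeatureGen]
    age_range: tuple[float, float] = (50.0, 80.0)
    female_prob: float = 0.497

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not self.features:
            raise ValueError("at least one feature is required")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")


def default_features(
    n_features: int = 8, eta_sex: float = float(np.log(1.5)), eta_age: float = 0.0
) -> list[FeatureGen]:
    """Volume-like features: ~7% coefficient of variation, mild age decline,
    ~8% male mean offset, and the given sex effect on log residual SD."""
    feats = []
    for j in range(n_features):
        base = 1e4 * (j + 1)
        feats.append(
            FeatureGen(
                name=f"vol_{j + 1:02d}",
                base=base,
                age1=-0.004 * base,
                age2=-8e-5 * base,
                age3=2e-6 * base,
                sex_effect=0.08 * base,
                zeta=float(np.log(0.07 * base)),
                eta_sex=eta_sex,
                eta_age=eta_age,
            )
        )
    return feats


def default_config(
    n_subjects: int,
    n_features: int = 8,
    eta_sex: float = float(np.log(1.5)),
    **kwargs,
) -> GeneratorConfig:
    return GeneratorConfig(
        n_subjects=n_subjects,
        features=default_features(n_features, eta_sex=eta_sex),
        **kwargs,
    )


@dataclass
class GroundTruth:
    """Everything needed to recompute any subject's value and true centile."""

    config: GeneratorConfig
    age_years: np.ndarray
    sex: np.ndarray
    mean: np.ndarray       # (n, k) covariate-driven means
    sd: np.ndarray         # (n, k) covariate-driven residual SDs
    sitefree: np.ndarray   # (n, k) feature values before site effects
    feature_names: list[str] = field(default_factory=list)

    def centiles(self, values: np.ndarray | None = None) -> np.ndarray:
        """Analytic centiles under the generating (site-free) distribution.

        With no argument, scores the generated site-free values themselves.
        """
        y = self.sitefree if values is None else np.asarray(values, dtype=float)
        out = np.empty_like(y)
        for j, f in enumerate(self.config.features):
            if f.noise == "normal":
                out[:, j] = ndtr((y[:, j] - self.mean[:, j]) / self.sd[:, j])
            elif f.noise == "bccg":
                out[:, j] = bccg_cdf(
                    y[:, j], self.mean[:, j], self.sd[:, j] / self.mean[:, j], f.nu
                )
            else:
                raise ValueError(f"unsupported noise family: {f.noise!r}")
        return out


def generate_cohort(
    config: GeneratorConfig, seed=None, batch=None
) -> tuple[Cohort, GroundTruth]:
    """Draw a synthetic cohort; deterministic given the seed.

    ``batch`` optionally attaches precomputed site labels; otherwise all
    subjects carry the single label "pooled" until sites are assigned.
    """
    rng = np.random.default_rng(seed)
    n = config.n_subjects
    lo, hi = config.age_range
    age_years = rng.uniform(lo, hi, size=n)
    sex = (rng.random(n) >= config.female_prob).astype(int)

    k = len(config.features)
    mean = np.empty((n, k))
    sd = np.empty((n, k))
    y = np.empty((n, k))
    a = age_years - REF_AGE_YEARS
    eps = rng.standard_normal((n, k))
    for j, f in enumerate(config.features):
        mean[:, j] = (
            f.base + f.age1 * a + f.age2 * a**2 + f.age3 * a**3
            + f.sex_effect * sex
        )
        sd[:, j] = np.exp(f.zeta + f.eta_sex * sex + f.eta_age * a)
        if f.noise == "normal":
            y[:, j] = mean[:, j] + sd[:, j] * eps[:, j]
        elif f.noise == "bccg":
            u = np.clip(ndtr(eps[:, j]), 1e-12, 1 - 1e-12)
            y[:, j] = bccg_quantile(u, mean[:, j], sd[:, j] / mean[:, j], f.nu)
        else:
            raise ValueError(f"unsupported noise family: {f.noise!r}")

    names = [f.name for f in config.features]
    index = pd.RangeIndex(n, name="subject_id")
    covariates = pd.DataFrame(
        {
            "age": age_years * DAYS_PER_YEAR,
            "sex": sex,
            "batch": np.asarray(batch) if batch is not None else "pooled",
        },
        index=index,
    )
    cohort = Cohort(
        features=pd.DataFrame(y, index=index, columns=names),
        covariates=covariates,
    )
    truth = GroundTruth(
        config=config,
        age_years=age_years,
        sex=sex,
        mean=mean,
        sd=sd,
        sitefree=y.copy(),
        feature_names=names,
    )
    return cohort, truth


def assign_sites_weighted(
    sex,
    probs: np.ndarray | None = None,
    seed=None,
    site_names: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Assign each subject to a site with sex-dependent probabilities.

    ``probs`` has one row per sex (female, male) summing to 1; the default is
    the three-site design with one balanced and two sex-imbalanced sites.
    """
    rng = np.random.default_rng(seed)
    sex = np.asarray(sex, dtype=int)
    probs = DEFAULT_THREE_SITE_PROBS if probs is None else np.asarray(probs, float)
    if probs.ndim != 2 or probs.shape[0] != 2:
        raise ValueError("probs must have shape (2, n_sites)")
    if np.any(probs < 0):
        raise ValueError("assignment probabilities must be nonnegative")
    if not np.allclose(probs.sum(axis=1), 1.0):
        raise ValueError("assignment probabilities must sum to 1 per sex")
    m = probs.shape[1]
    if site_names is None:
        site_names = tuple(f"site{chr(ord('A') + i)}" for i in range(m))
    cum = np.cumsum(probs, axis=1)
    u = rng.random(len(sex))
    idx = (u[:, None] > cum[sex]).sum(axis=1)
    return np.asarray(site_names, dtype=object)[idx]


def ratio_sweep_assignments(
    sex,
    n_site: int = 9400,
    step_fraction: float = 0.1,
    seed=None,
    site_names: tuple[str, str] = ("balanced", "varied"),
) -> list[pd.Series]:
    """Two-site designs sweeping the second site's male fraction 0 -> 1.

    Site 1 always holds ``n_site/2`` of each sex; site 2 holds ``j * step *
    n_site`` males and the complement of females, for ``j = 0 .. 1/step``.
    Subjects are sampled without replacement within sex for every design.
    Returns ``1/step + 1`` assignments as Series of site labels indexed by
    subject position.
    """
    rng = np.random.default_rng(seed)
    sex = np.asarray(sex, dtype=int)
    n_steps = round(1.0 / step_fraction)
    if abs(n_steps * step_fraction - 1.0) > 1e-9:
        raise ValueError("step_fraction must divide 1 evenly")
    if n_site % 2:
        raise ValueError("n_site must be even (balanced site)")
    males = np.flatnonzero(sex == 1)
    females = np.flatnonzero(sex == 0)
    need = n_site // 2 + n_site
    for label, pool in (("male", males), ("female", females)):
        if len(pool) < need:
            raise ValueError(
                f"need at least {need} {label} subjects, have {len(pool)}"
            )
    out = []
    for j in range(n_steps + 1):
        k_male = round(j * step_fraction * n_site)
        m_draw = rng.choice(males, size=n_site // 2 + k_male, replace=False)
        f_draw = rng.choice(
            females, size=n_site // 2 + (n_site - k_male), replace=False
        )
        labels = {}
        for idx in m_draw[: n_site // 2]:
            labels[idx] = site_names[0]
        for idx in m_draw[n_site // 2:]:
            labels[idx] = site_names[1]
        for idx in f_draw[: n_site // 2]:
            labels[idx] = site_names[0]
        for idx in f_draw[n_site // 2:]:
            labels[idx] = site_names[1]
        s = pd.Series(labels, name=f"male_frac_{j * step_fraction:.2f}")
        out.append(s.sort_index())
    return out


def inject_site_effects(
    cohort: Cohort,
    truth: GroundTruth,
    shift_sd: dict[str, float],
    scale: dict[str, float],
) -> Cohort:
    """Overlay additive/multiplicative site effects on a site-free cohort.

    ``shift_sd[site]`` is the additive offset in units of each feature's mean
    residual SD; ``scale[site]`` multiplies the noise term.  The cohort's
    batch labels select which effect each subject receives.
    """
    batch = cohort.batch.to_numpy()
    levels = pd.unique(batch)
    missing = [lev for lev in levels if lev not in shift_sd or lev not in scale]
    if missing:
        raise ValueError(f"site effects not specified for: {missing}")
    sd_bar = truth.sd.mean(axis=0)
    y = truth.sitefree.copy()
    for lev in levels:
        idx = batch == lev
        gamma = shift_sd[lev] * sd_bar
        delta = scale[lev]
        if delta <= 0:
            raise ValueError("multiplicative site effects must be positive")
        y[idx] = truth.mean[idx] + gamma + delta * (y[idx] - truth.mean[idx])
    feats = pd.DataFrame(y, index=cohort.features.index,
                         columns=cohort.features.columns)
    return Cohort(features=feats, covariates=cohort.covariates.copy(),
                  log_scale=cohort.log_scale)


def with_batch(cohort: Cohort, labels) -> Cohort:
    """Return a copy of the cohort with new batch labels."""
    cov = cohort.covariates.copy()
    cov["batch"] = np.asarray(labels)
    return Cohort(features=cohort.features.copy(), covariates=cov,
                  log_scale=cohort.log_scale, n_dropped=cohort.n_dropped)


def true_centiles(truth: GroundTruth, values: np.ndarray | None = None) -> np.ndarray:
    """Analytic ground-truth centiles (see :meth:`GroundTruth.centiles`)."""
    return truth.centiles(values)
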