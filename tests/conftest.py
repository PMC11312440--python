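import numpy as np
import pytest

from combatls import (
    FeatureGen,
    GeneratorConfig,
    assign_sites_weighted,
    generate_cohort,
    with_batch,
)


def small_config(n_subjects=600, n_features=3, eta_sex=float(np.log(1.3))):
    """O(1)-scale features so absolute tolerances are meaningful."""
    feats = [
        FeatureGen(
            name=f"f{j}",
            base=10.0 + j,
            age1=-0.02,
            age2=-0.001,
            sex_effect=0.5,
            zeta=float(np.log(0.7)),
            eta_sex=eta_sex,
        )
        for j in range(n_features)
    ]
    return GeneratorConfig(n_subjects=n_subjects, features=feats)


@pytest.fixture(scope="session")
def three_site_cohort():
    cohort, truth = generate_cohort(small_config(), seed=11)
    labels = assign_sites_weighted(truth.sex, seed=12)
    return with_batch(cohort, labels), truth


@pytest.fixture(scope="session")
def pooled_cohort():
    return generate_cohort(small_config(n_subjects=500), seed=21)
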