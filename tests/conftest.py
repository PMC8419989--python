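import numpy as np
import pytest

from lesionrad.model import MMRFModel
from lesionrad.synthetic import SynthConfig, generate_feature_cohort, split_train_test

PHENOTYPE_5 = [
    "H-T2-original-firstorder-Energy",
    "H-T2-original-firstorder-Entropy",
    "H-MPR-original-firstorder-Energy",
    "H-MPR-original-firstorder-Entropy",
    "edss",
]


@pytest.fixture(scope="session")
def cohort():
    """116-subject two-scanner cohort with 4 planted radiomic features (d=1.5)."""
    return generate_feature_cohort(SynthConfig(
        n_features=24, n_discriminative=4, effect_size=1.5,
        n_scanner_shifted=2, shift_size=2.0, clinical_effect_size=1.0, seed=3))


@pytest.fixture(scope="session")
def split(cohort):
    return split_train_test(cohort, 86, seed=1)


@pytest.fixture(scope="session")
def fitted(split):
    train, _ = split
    return MMRFModel(train, PHENOTYPE_5, n_trees=200, seed=0).fit(cv_folds=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
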