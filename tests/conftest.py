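"""Shared corpora and models, built once per session from the fixture grammar."""

import numpy as np
import pytest

from npscout.classify import train_rf
from npscout.datasets import dedup_and_deconflict, split_train_test
from npscout.features import FingerprintKind
from npscout.fixtures import FixtureSpec, make_labeled_library


@pytest.fixture(scope="session")
def small_library():
    """300+300 molecules, 5% decoy noise — the everyday test corpus."""
    return make_labeled_library(FixtureSpec(n_np=300, n_sm=300, seed=7, noise_rate=0.05))


@pytest.fixture(scope="session")
def clean_library():
    """150+150 noise-free molecules for separability/contrast assertions."""
    return make_labeled_library(FixtureSpec(n_np=150, n_sm=150, seed=13, noise_rate=0.0))


@pytest.fixture(scope="session")
def small_split(small_library):
    return split_train_test(small_library, ratio=(4, 1), seed=7)


@pytest.fixture(scope="session")
def maccs_matrix(small_split):
    train, _ = small_split
    return dedup_and_deconflict(train, FingerprintKind.MACCS166)


@pytest.fixture(scope="session")
def morgan_matrix(small_split):
    train, _ = small_split
    return dedup_and_deconflict(train, FingerprintKind.MORGAN2_1024)


@pytest.fixture(scope="session")
def maccs_model(maccs_matrix):
    return train_rf(maccs_matrix, seed=7)


@pytest.fixture(scope="session")
def morgan_model(morgan_matrix):
    return train_rf(morgan_matrix, seed=7)


@pytest.fixture(scope="session")
def study_library():
    """The full study-scale corpus: 2000 NP-like + 2000 SM-like, 5% noise."""
    return make_labeled_library(FixtureSpec(n_np=2000, n_sm=2000, seed=11, noise_rate=0.05))


@pytest.fixture(scope="session")
def study_split(study_library):
    return split_train_test(study_library, ratio=(4, 1), seed=11)


@pytest.fixture(scope="session")
def study_maccs_matrix(study_split):
    train, _ = study_split
    return dedup_and_deconflict(train, FingerprintKind.MACCS166)


@pytest.fixture(scope="session")
def study_morgan_matrix(study_split):
    train, _ = study_split
    return dedup_and_deconflict(train, FingerprintKind.MORGAN2_1024)


@pytest.fixture(scope="session")
def study_maccs_model(study_maccs_matrix):
    return train_rf(study_maccs_matrix, seed=11)


@pytest.fixture(scope="session")
def study_morgan_model(study_morgan_matrix):
    return train_rf(study_morgan_matrix, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
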