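"""Shared fixtures: synthetic corpora and fitted pipelines.

The heavy session-scoped fixtures (the default 31-subject calibration
corpus and its cross-validation reports) are computed once and shared by
the validation and acceptance tests.
"""

import numpy as np
import pytest

from mobiward import (
    ActivityPipeline,
    build_dataset,
    generate_cohort_sessions,
    kfold_cv,
    loso_cv,
)

#: seed of the default synthetic calibration corpus
CORPUS_SEED = 1
#: seed of the cross-validation machinery (fold shuffling, NCA, ANN)
CV_SEED = 0


@pytest.fixture(scope="session")
def corpus31():
    """The default 31-subject calibration corpus (study-sized)."""
    return generate_cohort_sessions(n_subjects=31, seed=CORPUS_SEED)


@pytest.fixture(scope="session")
def dataset31(corpus31):
    """Windowed 160-feature dataset of the default corpus (50% overlap)."""
    return build_dataset(corpus31)


@pytest.fixture(scope="session")
def kfold31(dataset31):
    return kfold_cv(dataset31, k=10, seed=CV_SEED)


@pytest.fixture(scope="session")
def loso31(dataset31):
    return loso_cv(dataset31, seed=CV_SEED)


@pytest.fixture(scope="session")
def small_corpus():
    """An 8-subject corpus for cheaper closed-loop tests."""
    return generate_cohort_sessions(n_subjects=8, seed=CORPUS_SEED)


@pytest.fixture(scope="session")
def small_dataset(small_corpus):
    return build_dataset(small_corpus)


@pytest.fixture(scope="session")
def trained_pipeline(small_dataset):
    """A pipeline fitted on the 8-subject corpus (matched generator)."""
    return ActivityPipeline().fit(small_dataset, seed=CV_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
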