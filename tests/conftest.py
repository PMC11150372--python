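import numpy as np
import pytest

from kinfate import (
    GeneratorConfig,
    TransformSpec,
    generate_cohort,
    preprocess_cohort,
    transform_cohort,
)
from kinfate.ensemble import MeanAggregator, compact_base_roster
from sklearn.linear_model import LogisticRegression


@pytest.fixture(scope="session")
def default_cohort():
    """Mid-size cohort under the canonical study conditions."""
    return generate_cohort(GeneratorConfig(n_cells=400, seed=42))


@pytest.fixture(scope="session")
def preprocessed(default_cohort):
    return preprocess_cohort(default_cohort, seed=43)


@pytest.fixture(scope="session")
def dwt_features(preprocessed):
    return transform_cohort(preprocessed, TransformSpec())


@pytest.fixture(scope="session")
def labels(preprocessed):
    return preprocessed.cohort.labels


def linear_stacker_roster():
    return [("mean", MeanAggregator()),
            ("stack_lr", LogisticRegression(max_iter=2000))]


@pytest.fixture(scope="session")
def fitted_model(dwt_features, labels):
    from kinfate import EnsembleIntegrationClassifier

    return EnsembleIntegrationClassifier(
        base_roster=compact_base_roster(),
        stacker_roster=linear_stacker_roster(),
        random_state=7,
    ).fit(dwt_features, labels)
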