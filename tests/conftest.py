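import numpy as np
import pytest

from facespace.annotation import ExemplarDB, train_part_detectors
from facespace.geometry import generalized_procrustes_mean
from facespace.synthetic import sketch_cohort


@pytest.fixture(scope="session")
def cohort24():
    """24 rendered sketches with individual shape variation."""
    return sketch_cohort(24, seed=7)


@pytest.fixture(scope="session")
def exemplar_db(cohort24):
    return ExemplarDB.from_c36([c for _, c in cohort24[:20]])


@pytest.fixture(scope="session")
def part_bank(cohort24):
    """Part detectors trained on the first 20 sketches."""
    return train_part_detectors(cohort24[:20], seed=0)


@pytest.fixture(scope="session")
def cohort_mean(cohort24):
    return generalized_procrustes_mean([c for _, c in cohort24])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
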