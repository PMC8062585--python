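"""Shared fixtures: a small simulated screen and quickly trained models."""

import warnings

import numpy as np
import pytest

from mlpd import models, pd_sim, seqdata
from mlpd._util import derive_rng, random_sequences


@pytest.fixture(scope="session")
def oracle():
    return pd_sim.AffinityOracle(seed=1)


@pytest.fixture(scope="session")
def train_ladder():
    return pd_sim.StringencyLadder.training_default()


@pytest.fixture(scope="session")
def small_experiment(oracle, train_ladder):
    """400-sequence two-round screen on the three-level training ladder."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pd_sim.simulate_experiment(
            pd_sim.SimConfig(library_size=400), train_ladder, oracle, seed=3
        )


@pytest.fixture(scope="session")
def small_labels(small_experiment):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return seqdata.label_pools(small_experiment.table)


@pytest.fixture(scope="session")
def small_levels(small_labels):
    return seqdata.superbin(small_labels)


@pytest.fixture(scope="session")
def trained_superbin(small_levels):
    """A quickly trained SuperBin model for scorer-consuming tests."""
    data = models.make_training_targets("superbin", levels=small_levels)
    return models.train_formulation("superbin", data, seed=11)


@pytest.fixture()
def rng():
    return derive_rng(0, "tests")


@pytest.fixture(scope="session")
def random_40mers():
    return random_sequences(200, 40, derive_rng(7, "fixture_seqs"))
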