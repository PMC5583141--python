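import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import smilesrl as sr

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=FutureWarning,
                        module="sklearn.svm")


@pytest.fixture(scope="session")
def toy_corpus():
    """Small deterministic corpus for unit-level model tests."""
    return sr.make_toy_corpus(400, seed=11)


@pytest.fixture(scope="session")
def toy_vocab(toy_corpus):
    return sr.build_vocabulary(toy_corpus)


@pytest.fixture(scope="session")
def small_prior(toy_corpus, toy_vocab):
    """A quickly trained prior good enough for RL and evaluation tests."""
    model = sr.SmilesGRU(toy_vocab, n_layers=1, hidden_size=48,
                         update_gate_bias=1.0, random_state=0)
    model.fit(toy_corpus, sr.TrainConfig(n_steps=400, batch_size=64, seed=0))
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
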