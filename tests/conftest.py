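import numpy as np
import pytest
from hypothesis import settings

from infantsleep.core import BehavioralState, Hypnogram

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def beh(*tokens) -> Hypnogram:
    """Behavioral hypnogram from tokens like 'AS', ('QS', 3)."""
    labels = []
    for tok in tokens:
        if isinstance(tok, tuple):
            labels.extend([BehavioralState(tok[0])] * tok[1])
        else:
            labels.append(BehavioralState(tok))
    return Hypnogram(tuple(labels), label_space="behavioral")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_behavioral(rng, n_epochs: int) -> Hypnogram:
    """Random run-structured behavioral hypnogram (runs of 1-10 epochs)."""
    states = list(BehavioralState)
    labels = []
    while len(labels) < n_epochs:
        s = states[rng.integers(len(states))]
        labels.extend([s] * int(rng.integers(1, 11)))
    return Hypnogram(tuple(labels[:n_epochs]), label_space="behavioral")
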