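"""Shared fixtures: demo library, ground truth, and a trained ensemble.

The trained ensemble is expensive (a couple of minutes) and session-scoped;
every test that needs a real trained model shares it.
"""

from __future__ import annotations

import numpy as np
import pytest

from promdesign.model import (
    EncoderConfig,
    SequenceEncoder,
    small_architecture,
    small_train_config,
    train_ensemble,
)
from promdesign.scaffold import one_hot, sample_sequence
from promdesign.synthetic import demo_scaffold, make_ground_truth, true_activity


class LinearScorer:
    """Transparent linear stand-in for a model ensemble.

    Scores are ``bias + sum_p weights[base_p, p]``; the input gradient of
    this score is the weight matrix itself.  Used as a closed-form oracle
    in design and mutagenesis tests.
    """

    def __init__(self, weights: np.ndarray, bias: float = 0.0):
        self.weights = np.asarray(weights, dtype=float)  # (4, L)
        self.bias = bias

    def score_seqs(self, seqs, objective) -> np.ndarray:
        return np.array(
            [self.bias + float((self.weights * one_hot(s)).sum()) for s in seqs]
        )

    def objective_grad(self, x_seq, objective):
        value = self.bias + float((self.weights * x_seq).sum())
        return value, self.weights.copy()


@pytest.fixture(scope="session")
def demo_sc():
    return demo_scaffold()

@pytest.fixture(scope="session")
def demo_sc_inducible():
    return demo_scaffold(inducible=True)


@pytest.fixture(scope="session")
def demo_truth(demo_sc):
    return make_ground_truth(demo_sc, np.random.default_rng(7))


@pytest.fixture(scope="session")
def demo_dataset(demo_sc, demo_truth):
    """5,000 library members with additive ground-truth activities."""
    rng = np.random.default_rng(7)
    # same stream position as make_ground_truth consumers elsewhere is not
    # required; only internal consistency matters
    seqs = [sample_sequence(demo_sc, rng) for _ in range(5000)]
    y = np.array([[true_activity(demo_truth, s)[0]] for s in seqs])
    return seqs, y


@pytest.fixture(scope="session")
def trained_ensemble(demo_sc, demo_dataset):
    """Reduced 3-submodel ensemble trained on the demo library."""
    seqs, y = demo_dataset
    encoder = SequenceEncoder({"demo": demo_sc}, EncoderConfig(shift_max=0))
    return train_ensemble(
        seqs,
        y,
        "demo",
        encoder,
        small_architecture(),
        small_train_config(seed=3),
        k=3,
    )
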