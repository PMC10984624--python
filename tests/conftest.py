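"""Shared fixtures: seeded RNGs and tiny generative models."""

import numpy as np
import pytest

from sociometer.engine import (
    GenerativeModel,
    LikelihoodModel,
    PreferenceVector,
    TransitionModel,
    enumerate_policies,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_model(A, B, C, D, horizon, E=None, beta0=1.0):
    """Assemble a GenerativeModel from raw arrays with an exhaustive policy set."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if B.ndim == 2:
        B = B[:, :, None]
    policies = enumerate_policies(B.shape[2], horizon)
    if E is None:
        E = np.full(len(policies), 1.0 / len(policies))
    return GenerativeModel(
        A=LikelihoodModel(A),
        B=TransitionModel(B),
        C=PreferenceVector(np.asarray(C, dtype=float)),
        D=np.asarray(D, dtype=float),
        E=np.asarray(E, dtype=float),
        policies=policies,
        horizon=horizon,
        beta0=beta0,
    )


@pytest.fixture
def make_tiny_model():
    return tiny_model
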