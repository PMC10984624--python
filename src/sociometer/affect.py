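"""Affective charge, precision-belief updating and valence labelling.

Affective charge (AC) measures how policy beliefs shifted relative to the
expected free energies of the policies: it is positive exactly when an
observation moved belief toward policies with lower-than-expected free
energy (things went better than anticipated), and negative in the opposite
case.  AC updates the agent's precision belief over the expected-free-
energy term: the posterior rate is ``beta_post = beta0 - AC`` (clamped
below), and the precision is its reciprocal, so good news sharpens policy
selection and bad news loosens it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BETA_MIN",
    "PrecisionBelief",
    "AffectiveCharge",
    "valence_label",
    "compute_affective_charge",
    "update_precision",
]

#: Lower clamp on the posterior rate so precision stays finite.
BETA_MIN = 0.05


@dataclass(frozen=True)
class PrecisionBelief:
    """Gamma-style belief over policy precision: rate ``beta``, precision ``1/beta``."""

    beta0: float
    beta_post: float

    def __post_init__(self) -> None:
        if self.beta0 <= 0 or self.beta_post <= 0:
            raise ValueError("rates must be strictly positive")

    @classmethod
    def from_prior(cls, beta0: float) -> "PrecisionBelief":
        return cls(beta0=beta0, beta_post=beta0)

    @property
    def gamma(self) -> float:
        return 1.0 / self.beta_post


def valence_label(ac_value: float, deadband: float = 0.0) -> str:
    """Map an affective-charge value to {negative, neutral, positive}.

    Values within ``deadband`` of zero are neutral.
    """
    if deadband < 0:
        raise ValueError("deadband must be non-negative")
    if ac_value > deadband:
        return "positive"
    if ac_value < -deadband:
        return "negative"
    return "neutral"


@dataclass(frozen=True)
class AffectiveCharge:
    """An affective-charge value (nats) with its valence label."""

    value: float
    valence: str

    @classmethod
    def from_value(cls, value: float, deadband: float = 0.0) -> "AffectiveCharge":
        return cls(value=float(value), valence=valence_label(value, deadband))


def compute_affective_charge(
    prior_policy,
    posterior_policy,
    efe_per_policy,
    *,
    deadband: float = 0.0,
) -> AffectiveCharge:
    """AC = (prior - posterior) . G.

    Positive exactly when the posterior places more mass than the prior on
    policies whose expected free energy is below the prior average; zero
    when beliefs did not move or when G is constant across policies.
    """
    prior = np.asarray(prior_policy, dtype=float)
    posterior = np.asarray(posterior_policy, dtype=float)
    G = np.asarray(efe_per_policy, dtype=float)
    if not (prior.shape == posterior.shape == G.shape):
        raise ValueError("prior, posterior and G must be aligned")
    return AffectiveCharge.from_value(float((prior - posterior) @ G), deadband)


def update_precision(
    belief: PrecisionBelief,
    ac: AffectiveCharge,
    *,
    beta_min: float = BETA_MIN,
) -> PrecisionBelief:
    """One-shot precision update from the prior rate.

    ``beta_post = max(beta0 - AC, beta_min)``; positive charge strictly
    increases precision and negative charge strictly decreases it until the
    clamp engages.
    """
    beta_post = max(belief.beta0 - ac.value, beta_min)
    return PrecisionBelief(beta0=belief.beta0, beta_post=beta_post)
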