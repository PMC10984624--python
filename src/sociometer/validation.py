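"""Brute-force reference computations for small models.

These functions deliberately avoid the engine's vectorised code paths: the
posterior comes from exhaustive enumeration of state sequences and the
expected free energy from a term-by-term double sum.  They are exponential
in the horizon and meant only for cross-checking the engine on models with
a handful of states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .engine import EPS, GenerativeModel

__all__ = ["ExactPosterior", "enumerate_posterior", "efe_direct", "random_model"]


@dataclass(frozen=True)
class ExactPosterior:
    """Exact posterior over state sequences for one policy."""

    joint: np.ndarray          # shape (S,) * T, sums to 1
    marginals: list            # per-timestep (S,) arrays
    log_evidence: float        # ln P(observations | policy)


def enumerate_posterior(
    model: GenerativeModel,
    policy: Sequence[int],
    observations: Sequence[int],
) -> ExactPosterior:
    """Posterior and evidence by summing over every state sequence."""
    actions = np.asarray(policy, dtype=int).ravel()
    observations = list(observations)
    S, T = model.n_states, model.horizon
    A, B, D = model.A.table, model.B.tables, model.D

    joint = np.zeros((S,) * T)
    for seq in np.ndindex(*joint.shape):
        p = D[seq[0]]
        for t in range(1, T):
            p *= B[seq[t], seq[t - 1], actions[t - 1]]
        for t, o in enumerate(observations):
            p *= A[o, seq[t]]
        joint[seq] = p
    evidence = float(joint.sum())
    if evidence <= 0:
        raise ValueError("observations have zero probability under the model")
    joint = joint / evidence
    marginals = [joint.sum(axis=tuple(i for i in range(T) if i != t)) for t in range(T)]
    return ExactPosterior(joint=joint, marginals=marginals, log_evidence=float(np.log(evidence)))


def efe_direct(
    model: GenerativeModel,
    policy: Sequence[int],
    beliefs: Sequence[np.ndarray],
    *,
    n_observed: int = 1,
) -> float:
    """Expected free energy as a direct expectation, term by term.

    Under the predictive distribution ``Q~(o, s) = Q(s|policy) P(o|s)`` the
    expected free energy of a future timestep is
    ``E[ln o_pred(o) - ln C(o) - ln P(o|s)]`` summed over every (state,
    outcome) pair; this rearranges the risk + ambiguity form used by the
    engine and must agree with it to numerical precision.
    """
    A = model.A.table
    total = 0.0
    for t in range(n_observed, model.horizon):
        s = np.asarray(beliefs[t], dtype=float)
        o_pred = A @ s
        lnC = model.C.log_dist(t)
        for i in range(model.n_states):
            for o in range(model.n_obs):
                w = s[i] * A[o, i]
                if w <= 0:
                    continue
                total += w * (
                    np.log(o_pred[o] + EPS) - lnC[o] - np.log(A[o, i] + EPS)
                )
    return float(total)


def random_model(
    rng: np.random.Generator,
    *,
    n_states: int = 2,
    n_obs: int = 2,
    n_actions: int = 2,
    horizon: int = 2,
) -> GenerativeModel:
    """A random small generative model with Dirichlet(1) columns.

    Used for the seeded cross-check suites; preferences are mild random
    log-weights and the policy set is exhaustive.
    """
    from .engine import (
        GenerativeModel,
        LikelihoodModel,
        PreferenceVector,
        TransitionModel,
        enumerate_policies,
    )

    A = rng.dirichlet(np.ones(n_obs), size=n_states).T
    B = np.stack(
        [rng.dirichlet(np.ones(n_states), size=n_states).T for _ in range(n_actions)],
        axis=2,
    )
    D = rng.dirichlet(np.ones(n_states))
    policies = enumerate_policies(n_actions, horizon)
    E = rng.dirichlet(np.ones(len(policies)))
    C = rng.normal(scale=1.0, size=n_obs)
    return GenerativeModel(
        A=LikelihoodModel(A),
        B=TransitionModel(B),
        C=PreferenceVector(C),
        D=D,
        E=E,
        policies=policies,
        horizon=horizon,
    )
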