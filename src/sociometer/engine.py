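"""Single-level discrete-state active-inference engine.

A generative model here is a categorical POMDP: a likelihood ``A`` mapping
hidden states to outcomes, action-conditioned transitions ``B``, log-scale
outcome preferences ``C``, an initial-state prior ``D`` and a habit prior
``E`` over policies (fixed action sequences).  Perception is a damped
fixed-point iteration over per-timestep state marginals under a mean-field
factorisation; planning scores each policy by its expected free energy
(risk plus ambiguity); decision combines habits, evidence and precision-
weighted expected free energy in a softmax; learning accumulates Dirichlet
concentration parameters that shadow ``A``, ``B``, ``D`` and ``E``.

Multiple hidden-state factors are always flattened to a single joint state
index at this level; factor structure is the concern of the model builders
in :mod:`sociometer.esteem`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "EPS",
    "Categorical",
    "LikelihoodModel",
    "TransitionModel",
    "PreferenceVector",
    "GenerativeModel",
    "StateInference",
    "VariationalFreeEnergy",
    "ExpectedFreeEnergy",
    "DirichletStore",
    "ExpectedModel",
    "softmax",
    "check_categorical",
    "enumerate_policies",
    "prune_policies",
    "infer_states",
    "compute_vfe",
    "compute_vfe_joint",
    "compute_efe",
    "policy_posterior",
    "select_action",
    "update_dirichlet",
    "expected_model",
]

#: Floor added inside every logarithm so that zero probabilities stay finite.
EPS = 1e-16

#: Defaults for the perceptual fixed-point iteration.
BELIEF_TOL = 1e-4
MAX_ITERS = 64
DAMPING = 0.5


def _ln(x: np.ndarray | float) -> np.ndarray:
    """Stabilised natural log, ``ln(x + EPS)``."""
    return np.log(np.asarray(x, dtype=float) + EPS)


def check_categorical(p, *, atol: float = 1e-10, name: str = "vector") -> np.ndarray:
    """Validate that ``p`` is a categorical distribution and return it as float64.

    Entries must be non-negative, sum to one within ``atol``, and the vector
    must have at least one entry.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError(f"{name} must be a non-empty 1-D vector, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValueError(f"{name} contains non-finite entries")
    if np.any(p < -atol):
        raise ValueError(f"{name} contains negative entries")
    total = float(p.sum())
    if abs(total - 1.0) > atol:
        raise ValueError(f"{name} sums to {total!r}, not 1")
    return p


@dataclass(frozen=True)
class Categorical:
    """A validated categorical distribution over a finite alphabet."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", check_categorical(self.probs, name="Categorical"))

    def __len__(self) -> int:
        return int(self.probs.size)

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self.probs, dtype=dtype)

    def entropy(self) -> float:
        """Shannon entropy in nats."""
        p = self.probs
        return float(-(p * _ln(p)).sum())


def _check_columns(table: np.ndarray, *, name: str, atol: float = 1e-8) -> None:
    sums = table.sum(axis=0)
    if np.any(table < -atol) or np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError(f"columns of {name} must be categorical distributions")


@dataclass(frozen=True)
class LikelihoodModel:
    """Conditional outcome table ``P(o | s)`` with one column per joint state."""

    table: np.ndarray  # (n_obs, n_states)

    def __post_init__(self) -> None:
        table = np.asarray(self.table, dtype=float)
        if table.ndim != 2:
            raise ValueError("likelihood table must be 2-D (n_obs, n_states)")
        _check_columns(table, name="A")
        object.__setattr__(self, "table", table)

    @property
    def n_obs(self) -> int:
        return self.table.shape[0]

    @property
    def n_states(self) -> int:
        return self.table.shape[1]

    @property
    def ambiguity(self) -> np.ndarray:
        """Per-state outcome entropy ``H[s]`` (nats); zero for deterministic columns.

        Recomputed on access so it always reflects the current table.
        """
        a = self.table
        h = -(a * _ln(a)).sum(axis=0)
        return np.maximum(h, 0.0)


@dataclass(frozen=True)
class TransitionModel:
    """Action-conditioned transition tables ``P(s' | s, u)``, shape (S, S, U)."""

    tables: np.ndarray

    def __post_init__(self) -> None:
        tables = np.asarray(self.tables, dtype=float)
        if tables.ndim != 3 or tables.shape[0] != tables.shape[1]:
            raise ValueError("transition tables must have shape (S, S, n_actions)")
        if tables.shape[2] < 1:
            raise ValueError("at least one action is required")
        for u in range(tables.shape[2]):
            _check_columns(tables[:, :, u], name=f"B[action={u}]")
        object.__setattr__(self, "tables", tables)

    @property
    def n_states(self) -> int:
        return self.tables.shape[0]

    @property
    def n_actions(self) -> int:
        return self.tables.shape[2]


@dataclass(frozen=True)
class PreferenceVector:
    """Outcome preferences on the natural-log scale (nats).

    Stored unnormalised; whenever preferences enter an expected-free-energy
    computation they are softmax-normalised so that only relative
    preferences matter.  May be a single vector shared by all timesteps,
    shape ``(n_obs,)``, or one column per timestep, shape ``(n_obs, T)``.
    """

    log_prefs: np.ndarray

    def __post_init__(self) -> None:
        lp = np.asarray(self.log_prefs, dtype=float)
        if lp.ndim not in (1, 2) or not np.all(np.isfinite(lp)):
            raise ValueError("log preferences must be a finite 1-D or 2-D array")
        object.__setattr__(self, "log_prefs", lp)

    def log_dist(self, tau: int = 0) -> np.ndarray:
        """Normalised log preference distribution for timestep ``tau``."""
        lp = self.log_prefs if self.log_prefs.ndim == 1 else self.log_prefs[:, min(tau, self.log_prefs.shape[1] - 1)]
        return lp - _logsumexp(lp)


def _logsumexp(x: np.ndarray) -> float:
    m = float(np.max(x))
    return m + float(np.log(np.exp(x - m).sum()))


@dataclass
class GenerativeModel:
    """One hierarchical level's generative model.

    Policies are rows of an integer array of shape ``(n_policies, horizon-1)``:
    one action per transition.  The trial runs over timesteps ``tau = 1..T``
    with the first observation preceding the first action, so a horizon of
    ``T`` implies ``T - 1`` actions per policy.
    """

    A: LikelihoodModel
    B: TransitionModel
    C: PreferenceVector
    D: np.ndarray
    E: np.ndarray
    policies: np.ndarray
    horizon: int
    beta0: float = 1.0
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.D = check_categorical(self.D, name="D")
        self.E = check_categorical(self.E, name="E")
        self.policies = np.asarray(self.policies, dtype=int)
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.policies.ndim != 2 or self.policies.shape[1] != self.horizon - 1:
            raise ValueError(
                f"policies must have shape (n_policies, horizon-1); got "
                f"{self.policies.shape} for horizon {self.horizon}"
            )
        if self.policies.shape[0] != self.E.size:
            raise ValueError("habit prior E must have one entry per policy")
        if self.A.n_states != self.B.n_states or self.D.size != self.A.n_states:
            raise ValueError("A, B and D disagree on the number of hidden states")
        if self.policies.size and (self.policies.min() < 0 or self.policies.max() >= self.B.n_actions):
            raise ValueError("policy action indices out of range")
        n_prefs = self.C.log_prefs.shape[0]
        if n_prefs != self.A.n_obs:
            raise ValueError("C must have one entry per outcome")
        if self.beta0 <= 0:
            raise ValueError("beta0 must be positive")

    @property
    def n_states(self) -> int:
        return self.A.n_states

    @property
    def n_obs(self) -> int:
        return self.A.n_obs

    @property
    def n_actions(self) -> int:
        return self.B.n_actions

    @property
    def n_policies(self) -> int:
        return self.policies.shape[0]


def enumerate_policies(n_actions: int, horizon: int) -> np.ndarray:
    """Exhaustive policy set: all action sequences of length ``horizon - 1``."""
    if n_actions < 1 or horizon < 1:
        raise ValueError("need n_actions >= 1 and horizon >= 1")
    seqs = list(itertools.product(range(n_actions), repeat=horizon - 1))
    return np.asarray(seqs, dtype=int).reshape(len(seqs), horizon - 1)


def prune_policies(policies: np.ndarray, E: np.ndarray, min_mass: float = 1e-6):
    """Drop policies whose habit mass falls below ``min_mass``; renormalise E."""
    E = np.asarray(E, dtype=float)
    keep = E >= min_mass
    if not np.any(keep):
        raise ValueError("pruning removed every policy")
    E_kept = E[keep]
    return policies[keep], E_kept / E_kept.sum()


def softmax(logits) -> np.ndarray:
    """Exp-normalisation; invariant to adding a constant to every logit."""
    x = np.asarray(logits, dtype=float)
    if x.size == 0:
        raise ValueError("softmax of an empty vector is undefined")
    x = x - np.max(x)
    e = np.exp(x)
    return e / e.sum()


# ---------------------------------------------------------------------------
# Perception
# ---------------------------------------------------------------------------


@dataclass
class StateInference:
    """Converged (or best-effort) per-timestep state marginals for one policy."""

    beliefs: list  # list of (n_states,) arrays, length = horizon
    converged: bool
    n_iters: int


def infer_states(
    model: GenerativeModel,
    policy: Sequence[int],
    observations: Sequence[int],
    *,
    tol: float = BELIEF_TOL,
    max_iters: int = MAX_ITERS,
) -> StateInference:
    """Fixed-point state inference for one policy given observations so far.

    Each timestep's belief is the softmax of the sum of three log messages:
    a past message carrying the initial prior and observations before
    ``tau`` forward through the policy's transitions, a future message
    carrying observations after ``tau`` backward through the transposed
    transitions, and the log-likelihood of ``tau``'s own observation where
    one exists.  The messages are the filtered forward and likelihood-
    weighted backward quantities (each observation enters exactly one
    message), so the fixed point coincides with the exact smoothing
    posterior of the chain; timesteps without observations receive the
    prior-predictive treatment.  Sweeps repeat until the largest absolute
    belief change drops below ``tol`` or ``max_iters`` is reached;
    non-convergence is flagged in the result, not fatal.
    """
    actions = np.asarray(policy, dtype=int).ravel()
    T = model.horizon
    if len(actions) != T - 1:
        raise ValueError(f"policy must supply {T - 1} actions, got {len(actions)}")
    observations = list(observations)
    if len(observations) > T:
        raise ValueError("more observations than timesteps")

    B = model.B.tables
    A = model.A.table
    ones = np.ones(model.n_states)

    beliefs = [model.D.copy() for _ in range(T)]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iters + 1):
        # Past messages: filtered forward chain.
        fwd = []
        pred = model.D.copy()
        for t in range(T):
            if t > 0:
                pred = B[:, :, actions[t - 1]] @ fwd[t - 1]
            a = pred * A[observations[t], :] if t < len(observations) else pred
            fwd.append(a / max(a.sum(), EPS))
        # Future messages: likelihood-weighted backward chain.
        bwd = [ones.copy() for _ in range(T)]
        for t in range(T - 2, -1, -1):
            lik = A[observations[t + 1], :] if t + 1 < len(observations) else ones
            v = B[:, :, actions[t]].T @ (lik * bwd[t + 1])
            bwd[t] = v / max(v.sum(), EPS)
        new_beliefs = [softmax(_ln(fwd[t]) + _ln(bwd[t])) for t in range(T)]
        delta = max(float(np.max(np.abs(nb - b))) for nb, b in zip(new_beliefs, beliefs))
        beliefs = new_beliefs
        if delta < tol:
            converged = True
            break
    return StateInference(beliefs=beliefs, converged=converged, n_iters=n_iter)


# ---------------------------------------------------------------------------
# Free energies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariationalFreeEnergy:
    """Variational free energy split into complexity and accuracy (nats)."""

    total: float
    complexity: float
    accuracy: float


def compute_vfe(
    model: GenerativeModel,
    policy: Sequence[int],
    beliefs: Sequence[np.ndarray],
    observations: Sequence[int],
) -> VariationalFreeEnergy:
    """Mean-field variational free energy of per-timestep marginals.

    Complexity is the divergence of the beliefs from the prior-propagated
    state chain under the policy; accuracy is the expected log-likelihood of
    the observed outcomes.  The total is complexity minus accuracy.
    """
    actions = np.asarray(policy, dtype=int).ravel()
    observations = list(observations)
    beliefs = [np.asarray(s, dtype=float) for s in beliefs]
    if len(beliefs) != model.horizon:
        raise ValueError("need one belief vector per timestep")

    B = model.B.tables
    eq = sum(float(s @ _ln(s)) for s in beliefs)
    e_prior = float(beliefs[0] @ _ln(model.D))
    for t in range(1, model.horizon):
        e_prior += float(beliefs[t] @ _ln(B[:, :, actions[t - 1]]) @ beliefs[t - 1])
    accuracy = 0.0
    for t, o in enumerate(observations):
        accuracy += float(_ln(model.A.table[o, :]) @ beliefs[t])
    complexity = eq - e_prior
    return VariationalFreeEnergy(total=complexity - accuracy, complexity=complexity, accuracy=accuracy)


def compute_vfe_joint(
    model: GenerativeModel,
    policy: Sequence[int],
    joint: np.ndarray,
    observations: Sequence[int],
) -> VariationalFreeEnergy:
    """Variational free energy of a joint belief over whole state sequences.

    ``joint`` has one axis per timestep, shape ``(S,) * horizon``.  This is
    the exact sequence-level functional: evaluated at the exact posterior it
    equals the negative log evidence of the observations under the policy.
    Intended for small, enumerable models (used by tests and validation).
    """
    actions = np.asarray(policy, dtype=int).ravel()
    observations = list(observations)
    joint = np.asarray(joint, dtype=float)
    S, T = model.n_states, model.horizon
    if joint.shape != (S,) * T:
        raise ValueError(f"joint belief must have shape {(S,) * T}")
    B, A = model.B.tables, model.A.table

    eq = e_prior = accuracy = 0.0
    for seq in np.ndindex(*joint.shape):
        q = float(joint[seq])
        if q <= 0.0:
            continue
        eq += q * float(_ln(q))
        lp = float(_ln(model.D[seq[0]]))
        for t in range(1, T):
            lp += float(_ln(B[seq[t], seq[t - 1], actions[t - 1]]))
        e_prior += q * lp
        ll = sum(float(_ln(A[o, seq[t]])) for t, o in enumerate(observations))
        accuracy += q * ll
    complexity = eq - e_prior
    return VariationalFreeEnergy(total=complexity - accuracy, complexity=complexity, accuracy=accuracy)


@dataclass(frozen=True)
class ExpectedFreeEnergy:
    """Per-future-timestep expected free energy and its decomposition (nats)."""

    total: float
    per_timestep: np.ndarray
    risk: np.ndarray
    ambiguity: np.ndarray
    taus: np.ndarray  # 0-based timestep indices the entries refer to


def compute_efe(
    model: GenerativeModel,
    policy: Sequence[int],
    beliefs: Sequence[np.ndarray],
    *,
    n_observed: int = 1,
) -> ExpectedFreeEnergy:
    """Expected free energy of a policy over its future timesteps.

    For each not-yet-observed timestep, predicted outcomes are
    ``o = A s``; risk is the divergence of ``o`` from the (normalised)
    preference distribution, and ambiguity is the expected outcome entropy
    ``s . H``.  Returns per-timestep values, both components, and the sum.
    """
    beliefs = [np.asarray(s, dtype=float) for s in beliefs]
    if len(beliefs) != model.horizon:
        raise ValueError("need one belief vector per timestep")
    A = model.A.table
    H = model.A.ambiguity
    taus, risks, ambiguities = [], [], []
    for t in range(n_observed, model.horizon):
        s = beliefs[t]
        o = A @ s
        lnC = model.C.log_dist(t)
        risks.append(float(o @ (_ln(o) - lnC)))
        ambiguities.append(float(s @ H))
        taus.append(t)
    risk = np.asarray(risks)
    ambiguity = np.asarray(ambiguities)
    per = risk + ambiguity
    return ExpectedFreeEnergy(
        total=float(per.sum()), per_timestep=per, risk=risk, ambiguity=ambiguity,
        taus=np.asarray(taus, dtype=int),
    )


# ---------------------------------------------------------------------------
# Decision
# ---------------------------------------------------------------------------


def policy_posterior(
    model: GenerativeModel,
    vfe_per_policy,
    efe_per_policy,
    gamma: float,
) -> Categorical:
    """Posterior over policies: softmax(ln E - F - gamma * G).

    Before any observation has arrived, ``F`` is the zero vector; pass the
    scalar ``0`` for that case.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    F = np.broadcast_to(np.asarray(vfe_per_policy, dtype=float), (model.n_policies,))
    G = np.broadcast_to(np.asarray(efe_per_policy, dtype=float), (model.n_policies,))
    return Categorical(softmax(_ln(model.E) - F - gamma * G))


def select_action(
    posterior: Categorical | np.ndarray,
    policies: np.ndarray,
    *,
    step: int = 0,
    mode: str = "sample",
    rng: np.random.Generator | None = None,
) -> int:
    """Marginalise the policy posterior onto the next action and pick one.

    The posterior mass of each policy accrues to its action at ``step`` (the
    first remaining action).  ``mode='sample'`` draws from that marginal
    using ``rng``; ``mode='map'`` takes the argmax, breaking ties toward the
    lowest action index.
    """
    p = np.asarray(posterior, dtype=float)
    policies = np.asarray(policies, dtype=int)
    if policies.shape[0] != p.size or policies.shape[0] == 0:
        raise ValueError("posterior and policy set are misaligned or empty")
    n_actions = int(policies.max()) + 1 if policies.size else 1
    if policies.shape[1] == 0:
        return 0  # degenerate single-timestep model: only the null action
    marginal = np.bincount(policies[:, step], weights=p, minlength=n_actions)
    marginal = marginal / marginal.sum()
    if mode == "map":
        return int(np.argmax(marginal))
    if mode == "sample":
        if rng is None:
            raise ValueError("sampling requires an explicit rng")
        return int(rng.choice(n_actions, p=marginal))
    raise ValueError(f"unknown action-selection mode {mode!r}")


# ---------------------------------------------------------------------------
# Learning
# ---------------------------------------------------------------------------


@dataclass
class DirichletStore:
    """Dirichlet concentration parameters shadowing A, B, D and E."""

    a: np.ndarray
    b: np.ndarray
    d: np.ndarray
    e: np.ndarray

    def __post_init__(self) -> None:
        for name in ("a", "b", "d", "e"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(arr <= 0):
                raise ValueError(f"Dirichlet concentrations {name} must be strictly positive")
            setattr(self, name, arr)

    @classmethod
    def from_model(
        cls,
        model: GenerativeModel,
        *,
        concentration: float = 1.0,
        floor: float = 0.05,
    ) -> "DirichletStore":
        """Seed concentrations proportional to the model's current arrays.

        ``concentration`` scales how strongly the initial arrays resist new
        counts; ``floor`` keeps zero-probability cells strictly positive.
        """
        return cls(
            a=concentration * model.A.table + floor,
            b=concentration * model.B.tables + floor,
            d=concentration * model.D + floor,
            e=concentration * model.E + floor,
        )

    def copy(self) -> "DirichletStore":
        return DirichletStore(self.a.copy(), self.b.copy(), self.d.copy(), self.e.copy())


def update_dirichlet(
    store: DirichletStore,
    beliefs: Sequence[np.ndarray],
    observations: Sequence[int],
    actions: Sequence[int],
    *,
    policy_posterior: np.ndarray | None = None,
    learning_rate: float = 1.0,
) -> DirichletStore:
    """Accumulate one completed trial's evidence into a new store.

    Counting rules: each observed timestep adds ``rate * o_onehot (x) belief``
    to ``a``; each taken action adds ``rate * belief(t+1) (x) belief(t)`` to
    that action's slice of ``b``; the first belief is added to ``d``; the
    trial's policy posterior is added to ``e`` when habit learning is on
    (``policy_posterior`` given).  Returns a copy; the input is untouched.
    """
    if learning_rate <= 0:
        raise ValueError("learning_rate must be positive")
    out = store.copy()
    beliefs = [np.asarray(s, dtype=float) for s in beliefs]
    for t, o in enumerate(observations):
        out.a[o, :] += learning_rate * beliefs[t]
    for t, u in enumerate(actions):
        out.b[:, :, u] += learning_rate * np.outer(beliefs[t + 1], beliefs[t])
    out.d += learning_rate * beliefs[0]
    if policy_posterior is not None:
        out.e += learning_rate * np.asarray(policy_posterior, dtype=float)
    return out


@dataclass(frozen=True)
class ExpectedModel:
    """Normalised Dirichlet means packaged as model components."""

    A: LikelihoodModel
    B: TransitionModel
    D: np.ndarray
    E: np.ndarray


def expected_model(store: DirichletStore) -> ExpectedModel:
    """Posterior-mean model: every conditional is its normalised concentration."""
    a = store.a / store.a.sum(axis=0, keepdims=True)
    b = store.b / store.b.sum(axis=0, keepdims=True)
    d = store.d / store.d.sum()
    e = store.e / store.e.sum()
    return ExpectedModel(A=LikelihoodModel(a), B=TransitionModel(b), D=d, E=e)
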