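"""Two-level generative model of self-esteem and the agent loop.

The lower (state) level is a fast sociometer: within each trial the agent
infers a joint hidden state made of an *ideal image* (binary
competence / social-conformity / physical-attractiveness components, or a
collapsed three-level factor) and a *self-image* (how well the agent
currently aligns with that ideal), observes social feedback, prefers
approval, and chooses between engaging, conforming and withdrawing.

The upper (trait) level is slow: every ``slow_horizon`` trials the lower
level's results are summarised into a discrete observation (dominant
valence of the affective-charge trace, plus the final self-image bin) and
fed to a perception-and-learning-only model over trait self-esteem
{low, medium, high} crossed with core valence {negative, neutral,
positive}.  The inferred trait feeds back down as a set of empirical
priors: it modulates the precision of the lower-level transition model
(a power-law temperature on the columns of B), sets the prior policy
precision, and can optionally tilt the habit prior.  High trait therefore
produces sharper transition expectations and more deterministic action
selection; low trait produces flatter expectations and more volatile
behaviour.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .affect import AffectiveCharge, PrecisionBelief, compute_affective_charge, update_precision
from .engine import (
    Categorical,
    DirichletStore,
    GenerativeModel,
    LikelihoodModel,
    PreferenceVector,
    TransitionModel,
    compute_efe,
    compute_vfe,
    expected_model,
    infer_states,
    policy_posterior,
    select_action,
    softmax,
    update_dirichlet,
)
from . import niche as niche_mod

__all__ = [
    "TRAITS",
    "VALENCES",
    "ACTIONS",
    "StateLevelSpec",
    "TraitLevelSpec",
    "TraitLink",
    "LearningConfig",
    "HierarchicalAgent",
    "TrialRecord",
    "RunResult",
    "build_state_level",
    "build_trait_level",
    "apply_trait_modulation",
    "self_image_marginal",
    "summarize_trial",
    "trait_step",
    "run_agent",
]

TRAITS = ("low", "medium", "high")
VALENCES = ("negative", "neutral", "positive")
ACTIONS = ("engage", "conform", "withdraw")

_IDEAL_COMPONENTS = ("competence", "social_conformity", "physical_attractiveness")


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StateLevelSpec:
    """Structure of the fast sociometer level.

    ``collapse_ideal`` replaces the three binary ideal-image components with
    a single three-level factor (cheaper joint state space).  ``drift`` is
    the signed probability that an action moves the self-image one level
    toward (positive) or away from (negative) alignment per step.
    ``preference_strength`` is the log-preference gap, in nats, between
    approval and neutral (rejection sits symmetrically below neutral).
    """

    collapse_ideal: bool = False
    self_image_levels: int = 3
    n_feedback: int = 3
    drift: tuple = (0.6, 0.3, -0.5)  # engage, conform, withdraw
    preference_strength: float = 3.0
    horizon: int = 2

    def __post_init__(self) -> None:
        if self.self_image_levels < 2:
            raise ValueError("self-image needs at least 2 levels")
        if self.n_feedback not in (2, 3):
            raise ValueError("feedback alphabet must have 2 or 3 outcomes")
        if len(self.drift) != len(ACTIONS) or any(abs(d) > 1 for d in self.drift):
            raise ValueError("drift needs one signed probability per action")
        if self.horizon < 2:
            raise ValueError("a trial needs at least two timesteps")

    @property
    def factor_shape(self) -> tuple:
        ideal = (3,) if self.collapse_ideal else (2, 2, 2)
        return ideal + (self.self_image_levels,)


@dataclass(frozen=True)
class TraitLevelSpec:
    """Structure of the slow trait level.

    ``slow_horizon`` is the number of lower-level trials summarised into one
    trait step.  ``likelihood_dominance`` is the weakly informative diagonal
    mass of the initial upper likelihood; trait and valence stickiness set
    how slowly the two upper factors are expected to move per trait step.
    """

    slow_horizon: int = 10
    likelihood_dominance: float = 0.6
    trait_stickiness: float = 0.95
    valence_stickiness: float = 0.5

    def __post_init__(self) -> None:
        if self.slow_horizon < 1:
            raise ValueError("slow horizon must be >= 1")
        if not 1 / 3 <= self.likelihood_dominance <= 1:
            raise ValueError("likelihood dominance must lie in [1/3, 1]")


@dataclass(frozen=True)
class TraitLink:
    """How the inferred trait modulates the lower level.

    ``omega`` is the per-trait precision exponent applied to the lower
    transition columns (1 is neutral; larger sharpens, smaller flattens);
    ``gamma0`` the per-trait prior policy precision; ``e_tilt`` an optional
    per-trait multiplicative reweighting of the habit prior by first action.
    """

    omega: dict = field(default_factory=lambda: {"low": 0.5, "medium": 1.0, "high": 2.0})
    gamma0: dict = field(default_factory=lambda: {"low": 0.5, "medium": 1.0, "high": 2.0})
    e_tilt: dict | None = None

    def __post_init__(self) -> None:
        for name, mapping in (("omega", self.omega), ("gamma0", self.gamma0)):
            if set(mapping) != set(TRAITS) or any(v <= 0 for v in mapping.values()):
                raise ValueError(f"{name} must map every trait level to a positive value")
        if not self.omega["high"] > self.omega["medium"] > self.omega["low"]:
            raise ValueError("omega must increase strictly with trait level")

    @classmethod
    def neutral(cls) -> "TraitLink":
        """A link whose modulation is switched off (used for ablations).

        ``omega`` and ``gamma0`` are 1 for every trait, so trait inference
        proceeds but has no effect on the lower level.  Bypasses the strict
        omega-ordering check on purpose.
        """
        link = cls.__new__(cls)
        object.__setattr__(link, "omega", {t: 1.0 for t in TRAITS})
        object.__setattr__(link, "gamma0", {t: 1.0 for t in TRAITS})
        object.__setattr__(link, "e_tilt", None)
        return link


@dataclass(frozen=True)
class LearningConfig:
    """Evidence-accumulation settings for the agent loop."""

    learn_a: bool = False
    learn_b: bool = True
    learn_d: bool = False
    learn_e: bool = False
    learning_rate: float = 1.0
    concentration: float = 20.0        # prior strength of lower-level counts
    upper_concentration: float = 10.0  # prior strength of upper-level counts
    memory: float = 0.9                # cross-trial carry-over of the state belief
    ac_deadband: float = 0.01          # neutral band for valence labelling

    def __post_init__(self) -> None:
        if not 0.0 <= self.memory <= 1.0:
            raise ValueError("memory must lie in [0, 1]")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


# ---------------------------------------------------------------------------
# Model builders
# ---------------------------------------------------------------------------


def _alignment_scores(spec: StateLevelSpec) -> np.ndarray:
    """Score in [0, 1] per joint state: how well the agent matches the ideal."""
    shape = spec.factor_shape
    K = spec.self_image_levels
    scores = np.empty(int(np.prod(shape)))
    for flat, idx in enumerate(np.ndindex(*shape)):
        ideal_levels = idx[:-1]
        if spec.collapse_ideal:
            ideal = ideal_levels[0] / 2.0
        else:
            ideal = sum(ideal_levels) / 3.0
        align = idx[-1] / (K - 1)
        scores[flat] = 0.5 * (ideal + align)
    return scores


def _self_image_transition(K: int, drift: float) -> np.ndarray:
    """One-step drift of the self-image: move one level toward (or away from)
    alignment with probability ``|drift|``, otherwise stay; ends absorb."""
    B = np.zeros((K, K))
    step = 1 if drift >= 0 else -1
    p = abs(drift)
    for k in range(K):
        k2 = min(max(k + step, 0), K - 1)
        B[k2, k] += p
        B[k, k] += 1.0 - p
    return B


def build_state_level(spec: StateLevelSpec, reliability: float = 0.9) -> GenerativeModel:
    """Construct the fast sociometer generative model.

    ``reliability`` is the probability that feedback signals the outcome the
    joint state deserves (its alignment score mapped to the nearest
    feedback anchor); the remaining mass spreads evenly over the other
    outcomes, so 1 gives deterministic columns and ``1/n_feedback`` gives
    uninformative ones.
    """
    if not 0.5 <= reliability <= 1.0:
        raise ValueError("feedback reliability must lie in [0.5, 1]")
    shape = spec.factor_shape
    S = int(np.prod(shape))
    m = spec.n_feedback

    # Likelihood: outcome anchors at 1 (approval) down to 0 (rejection).
    anchors = np.linspace(1.0, 0.0, m)
    scores = _alignment_scores(spec)
    A = np.full((m, S), (1.0 - reliability) / (m - 1))
    for s in range(S):
        signalled = int(np.argmin(np.abs(scores[s] - anchors)))
        A[signalled, s] = reliability

    # Transitions: ideal-image components are static; the self-image drifts
    # per action.  Joint order matches C-order flattening of factor_shape.
    ident = np.eye(int(np.prod(shape[:-1])))
    B = np.stack(
        [np.kron(ident, _self_image_transition(spec.self_image_levels, d)) for d in spec.drift],
        axis=2,
    )

    p = spec.preference_strength
    C = np.array([p, -p]) if m == 2 else np.array([p, 0.0, -p])
    # One policy per action, repeated across the trial.  At the default
    # horizon of 2 this is the exhaustive set; longer trials keep the same
    # three commitments (exhaustive enumeration is available via the engine).
    policies = np.repeat(np.arange(len(ACTIONS))[:, None], spec.horizon - 1, axis=1)
    E = np.full(len(policies), 1.0 / len(policies))

    return GenerativeModel(
        A=LikelihoodModel(A),
        B=TransitionModel(B),
        C=PreferenceVector(C),
        D=np.full(S, 1.0 / S),
        E=E,
        policies=policies,
        horizon=spec.horizon,
        labels={
            "factor_shape": shape,
            "actions": list(ACTIONS),
            "outcomes": ["approval", "rejection"] if m == 2 else ["approval", "neutral", "rejection"],
            "alignment_scores": scores.tolist(),
        },
    )


def _dominance_matrix(n: int, dominance: float) -> np.ndarray:
    off = (1.0 - dominance) / (n - 1)
    return np.full((n, n), off) + (dominance - off) * np.eye(n)


def _sticky(n: int, stickiness: float) -> np.ndarray:
    return stickiness * np.eye(n) + (1.0 - stickiness) / n * np.ones((n, n))


def build_trait_level(spec: TraitLevelSpec) -> GenerativeModel:
    """Construct the slow trait-level model (perception and learning only).

    Hidden state: trait {low, medium, high} x valence {negative, neutral,
    positive}; observation: trial summary (valence label x self-image bin);
    a single do-nothing policy, horizon equal to the slow horizon.  The
    likelihood starts weakly informative (diagonal dominance) and is meant
    to be refined by Dirichlet counts.
    """
    nt, nv = len(TRAITS), len(VALENCES)
    Pv = _dominance_matrix(nv, spec.likelihood_dominance)  # P(valence label | valence)
    Pb = _dominance_matrix(nt, spec.likelihood_dominance)  # P(self-image bin | trait)
    A = np.zeros((nv * nt, nt * nv))
    for t in range(nt):
        for v in range(nv):
            for vl in range(nv):
                for b in range(nt):
                    A[vl * nt + b, t * nv + v] = Pv[vl, v] * Pb[b, t]
    B = np.kron(_sticky(nt, spec.trait_stickiness), _sticky(nv, spec.valence_stickiness))[:, :, None]
    S = nt * nv
    T = max(spec.slow_horizon, 2)
    return GenerativeModel(
        A=LikelihoodModel(A),
        B=TransitionModel(B),
        C=PreferenceVector(np.zeros(nv * nt)),
        D=np.full(S, 1.0 / S),
        E=np.array([1.0]),
        policies=np.zeros((1, T - 1), dtype=int),
        horizon=T,
        labels={"traits": list(TRAITS), "valences": list(VALENCES)},
    )


def apply_trait_modulation(B: TransitionModel, omega: float) -> TransitionModel:
    """Power-law precision modulation of transition columns.

    Every column ``c`` becomes ``normalise(c ** omega)``: 1 is the identity,
    large ``omega`` sharpens columns toward their argmax and ``omega -> 0``
    flattens them toward uniform.  Preserves column stochasticity exactly
    and commutes with permutations of the states.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    if omega == 1.0:
        return B
    powered = np.power(B.tables, omega)
    powered = powered / powered.sum(axis=0, keepdims=True)
    return TransitionModel(powered)


def self_image_marginal(belief: np.ndarray, model: GenerativeModel) -> np.ndarray:
    """Marginal over self-image levels from a joint lower-level belief."""
    shape = tuple(model.labels["factor_shape"])
    joint = np.asarray(belief, dtype=float).reshape(shape)
    return joint.sum(axis=tuple(range(len(shape) - 1)))


# ---------------------------------------------------------------------------
# Trial summaries and the trait step
# ---------------------------------------------------------------------------


def summarize_trial(
    ac_values: Sequence[float],
    final_self_image: np.ndarray,
    *,
    n_bins: int = 3,
    deadband: float = 0.01,
):
    """Discretise one lower-level trial for the trait level.

    Returns ``(valence_index, bin_index, flat_observation)``: the dominant
    valence label is the sign of the mean affective charge (with a neutral
    deadband) indexed in {negative: 0, neutral: 1, positive: 2}; the
    self-image bin is the highest-mass bin of the final self-image
    posterior, coarsened onto ``n_bins`` bins when the self-image has more
    levels than bins.
    """
    from .affect import valence_label

    mean_ac = float(np.mean(ac_values)) if len(ac_values) else 0.0
    valence_idx = VALENCES.index(valence_label(mean_ac, deadband))
    p = np.asarray(final_self_image, dtype=float)
    level = int(np.argmax(p))
    bin_idx = min(level * n_bins // p.size, n_bins - 1)
    return valence_idx, bin_idx, valence_idx * n_bins + bin_idx


# ---------------------------------------------------------------------------
# The hierarchical agent
# ---------------------------------------------------------------------------


@dataclass
class HierarchicalAgent:
    """A two-level self-esteem agent: models, evidence stores and clocks.

    ``trait_clamp`` freezes the trait at a named level (the upper level is
    neither inferred nor updated), used for controlled comparisons.
    """

    state_spec: StateLevelSpec
    trait_spec: TraitLevelSpec
    link: TraitLink
    learning: LearningConfig
    reliability: float
    lower: GenerativeModel
    lower_store: DirichletStore
    upper: GenerativeModel
    upper_store: DirichletStore
    upper_prior: np.ndarray
    state_prior: np.ndarray
    precision: PrecisionBelief
    current_trait: str = "medium"
    trait_clamp: str | None = None
    trial_count: int = 0
    trait_step_count: int = 0

    @classmethod
    def build(
        cls,
        state_spec: StateLevelSpec | None = None,
        trait_spec: TraitLevelSpec | None = None,
        link: TraitLink | None = None,
        learning: LearningConfig | None = None,
        *,
        reliability: float = 0.9,
        trait_clamp: str | None = None,
    ) -> "HierarchicalAgent":
        state_spec = state_spec or StateLevelSpec()
        trait_spec = trait_spec or TraitLevelSpec()
        link = link or TraitLink()
        learning = learning or LearningConfig()
        if trait_clamp is not None and trait_clamp not in TRAITS:
            raise ValueError(f"trait_clamp must be one of {TRAITS}")
        lower = build_state_level(state_spec, reliability)
        upper = build_trait_level(trait_spec)
        trait0 = trait_clamp or "medium"
        return cls(
            state_spec=state_spec,
            trait_spec=trait_spec,
            link=link,
            learning=learning,
            reliability=reliability,
            lower=lower,
            lower_store=DirichletStore.from_model(lower, concentration=learning.concentration),
            upper=upper,
            upper_store=DirichletStore.from_model(upper, concentration=learning.upper_concentration),
            upper_prior=upper.D.copy(),
            state_prior=lower.D.copy(),
            precision=PrecisionBelief.from_prior(1.0 / link.gamma0[trait0]),
            current_trait=trait0,
            trait_clamp=trait_clamp,
        )

    # -- effective lower-level model under the current trait ---------------

    @property
    def effective_trait(self) -> str:
        return self.trait_clamp if self.trait_clamp is not None else self.current_trait

    def effective_model(self) -> GenerativeModel:
        """Lower-level model with learned arrays, trait-modulated B and the
        carried-over state prior."""
        learned = expected_model(self.lower_store)
        A = learned.A if self.learning.learn_a else self.lower.A
        B_base = learned.B if self.learning.learn_b else self.lower.B
        B = apply_trait_modulation(B_base, self.link.omega[self.effective_trait])
        E = learned.E if self.learning.learn_e else self.lower.E
        if self.link.e_tilt is not None:
            mult = np.asarray(self.link.e_tilt[self.effective_trait], dtype=float)
            E = E * mult[self.lower.policies[:, 0]]
            E = E / E.sum()
        return replace(self.lower, A=A, B=B, E=E, D=self.state_prior.copy())

    def trait_posterior(self) -> np.ndarray:
        """Current marginal belief over trait levels."""
        nt, nv = len(TRAITS), len(VALENCES)
        return self.upper_prior.reshape(nt, nv).sum(axis=1)


def trait_step(agent: HierarchicalAgent, summaries: Sequence[int]) -> dict:
    """One slow-timescale update from a block of trial summaries.

    Runs upper-level state inference on the summary observations, counts
    the evidence into the upper Dirichlet store, carries the propagated
    posterior forward as the next empirical prior, and re-derives the lower
    level's trait modulation (transition precision, prior policy precision,
    optional habit tilt) from the MAP trait.  Mutates ``agent`` in place and
    returns a summary dict.
    """
    T = agent.upper.horizon
    if len(summaries) != agent.trait_spec.slow_horizon:
        raise ValueError("summaries must cover exactly one slow horizon")
    obs = list(summaries)
    if len(obs) < T:  # slow_horizon == 1 edge: pad the horizon with no observation
        obs = obs[:T]
    learned = expected_model(agent.upper_store)
    model = replace(agent.upper, A=learned.A, D=agent.upper_prior.copy())
    res = infer_states(model, model.policies[0], obs)

    agent.upper_store = update_dirichlet(
        agent.upper_store, res.beliefs, obs, [], learning_rate=agent.learning.learning_rate,
    )
    final = res.beliefs[len(obs) - 1] if obs else res.beliefs[-1]
    agent.upper_prior = model.B.tables[:, :, 0] @ final

    nt, nv = len(TRAITS), len(VALENCES)
    trait_marginal = final.reshape(nt, nv).sum(axis=1)
    valence_marginal = final.reshape(nt, nv).sum(axis=0)
    map_trait = TRAITS[int(np.argmax(trait_marginal))]
    if agent.trait_clamp is None:
        agent.current_trait = map_trait
        beta0 = 1.0 / agent.link.gamma0[map_trait]
        agent.precision = PrecisionBelief(beta0=beta0, beta_post=agent.precision.beta_post)
    agent.trait_step_count += 1
    return {
        "step": agent.trait_step_count,
        "trial": agent.trial_count,
        "map_trait": map_trait,
        "trait_posterior": trait_marginal.tolist(),
        "valence_posterior": valence_marginal.tolist(),
        "omega": agent.link.omega[agent.effective_trait],
        "gamma0": agent.link.gamma0[agent.effective_trait],
    }


# ---------------------------------------------------------------------------
# The perception-action loop
# ---------------------------------------------------------------------------


@dataclass
class TrialRecord:
    """One lower-level timestep of a run."""

    trial: int
    tau: int
    observation: int
    action: int | None
    self_image_belief: list
    trait_map: str
    ac: float
    gamma: float
    policy_entropy: float
    vfe: float
    efe_selected: float

    def to_dict(self) -> dict:
        return {
            "trial": self.trial,
            "tau": self.tau,
            "observation": self.observation,
            "action": self.action,
            "self_image_belief": list(self.self_image_belief),
            "trait_map": self.trait_map,
            "ac": self.ac,
            "gamma": self.gamma,
            "policy_entropy": self.policy_entropy,
            "vfe": self.vfe,
            "efe_selected": self.efe_selected,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialRecord":
        return cls(**d)


@dataclass
class RunResult:
    """Full trajectory of a run plus the final agent state."""

    records: list
    trait_steps: list
    config: dict
    seed: int
    agent: HierarchicalAgent | None = None

    @property
    def n_trials(self) -> int:
        return self.config.get("n_trials", 0)

    def per_trial(self, key: str) -> np.ndarray:
        """One value per trial, taken from that trial's final timestep row."""
        T = self.config["horizon"]
        return np.asarray([getattr(r, key) for r in self.records[T - 1 :: T]])

    def actions(self) -> np.ndarray:
        T = self.config["horizon"]
        return np.asarray([r.action for r in self.records[0::T]])

    def self_image_alignment(self) -> np.ndarray:
        """Per trial, the belief mass on the top self-image level at the end."""
        T = self.config["horizon"]
        return np.asarray([r.self_image_belief[-1] for r in self.records[T - 1 :: T]])


def run_agent(
    agent: HierarchicalAgent,
    niche_config: "niche_mod.NicheConfig",
    n_trials: int,
    seed: int,
    *,
    mode: str = "sample",
) -> RunResult:
    """Run the full perceive-evaluate-decide-act-feel-learn loop.

    Per trial: draw a baseline observation, infer states per policy, score
    policies by expected free energy, form the policy posterior under the
    current precision, select and execute an action, receive niche
    feedback, re-infer, compute the affective charge between the pre- and
    post-feedback policy beliefs, update precision and Dirichlet stores,
    and carry the state belief forward.  Every slow horizon the trial
    summaries trigger a trait step.  The input agent is copied, never
    mutated; a fixed seed yields a bit-identical result.
    """
    if niche_config.n_actions != len(ACTIONS):
        raise ValueError("niche must define one approval probability per agent action")
    if niche_config.n_outcomes != agent.lower.n_obs:
        raise ValueError("niche feedback alphabet does not match the agent's likelihood")

    agent = copy.deepcopy(agent)
    rng = np.random.default_rng(seed)
    niche_state = niche_mod.make_niche(niche_config)

    records: list[TrialRecord] = []
    trait_steps: list[dict] = []
    summaries: list[int] = []
    T = agent.state_spec.horizon

    for trial in range(n_trials):
        model = agent.effective_model()
        o1 = niche_mod.draw_baseline(niche_state, rng)

        inferences = [infer_states(model, pol, [o1]) for pol in model.policies]
        F = np.array([compute_vfe(model, pol, inf.beliefs, [o1]).total
                      for pol, inf in zip(model.policies, inferences)])
        efes = [compute_efe(model, pol, inf.beliefs, n_observed=1)
                for pol, inf in zip(model.policies, inferences)]
        G = np.array([e.total for e in efes])

        gamma = agent.precision.gamma
        pi_prior = policy_posterior(model, 0.0, G, gamma)
        pi_decide = policy_posterior(model, F, G, gamma)
        action = select_action(pi_decide, model.policies, step=0, mode=mode, rng=rng)

        niche_state, o2 = niche_mod.niche_step(niche_state, action, rng)
        observations = [o1, o2]

        post_inferences = [infer_states(model, pol, observations) for pol in model.policies]
        F_post = np.array([compute_vfe(model, pol, inf.beliefs, observations).total
                           for pol, inf in zip(model.policies, post_inferences)])
        pi_post = policy_posterior(model, F_post, G, gamma)

        ac = compute_affective_charge(
            pi_prior.probs, pi_post.probs, G, deadband=agent.learning.ac_deadband,
        )
        agent.precision = update_precision(agent.precision, ac)

        w = pi_post.probs
        bma = [np.einsum("p,ps->s", w, np.stack([inf.beliefs[t] for inf in post_inferences]))
               for t in range(T)]
        agent.lower_store = update_dirichlet(
            agent.lower_store, bma, observations, [action] * (T - 1),
            policy_posterior=w if agent.learning.learn_e else None,
            learning_rate=agent.learning.learning_rate,
        )
        agent.state_prior = agent.learning.memory * bma[-1] + (
            1.0 - agent.learning.memory
        ) * np.full(model.n_states, 1.0 / model.n_states)

        sel = int(np.argmax(pi_decide.probs)) if mode == "map" else None
        # report the EFE of the policy whose first action was taken
        matching = np.flatnonzero(model.policies[:, 0] == action)
        efe_selected = float(G[matching[0]]) if matching.size else float("nan")
        vfe_bma = float(w @ F_post)
        entropy = pi_decide.entropy()

        si = [self_image_marginal(b, model) for b in bma]
        for t in range(T):
            records.append(
                TrialRecord(
                    trial=trial,
                    tau=t + 1,
                    observation=observations[t] if t < len(observations) else -1,
                    action=action if t == 0 else None,
                    self_image_belief=[float(x) for x in si[t]],
                    trait_map=agent.effective_trait,
                    ac=ac.value,
                    gamma=agent.precision.gamma,
                    policy_entropy=entropy,
                    vfe=vfe_bma,
                    efe_selected=efe_selected,
                )
            )

        agent.trial_count += 1
        _, _, flat = summarize_trial(
            [ac.value], si[-1], deadband=agent.learning.ac_deadband,
        )
        summaries.append(flat)
        if len(summaries) == agent.trait_spec.slow_horizon:
            if agent.trait_clamp is None:
                trait_steps.append(trait_step(agent, summaries))
            summaries = []

    config = {
        "niche": niche_config.to_dict(),
        "n_trials": n_trials,
        "horizon": T,
        "seed": seed,
        "mode": mode,
        "reliability": agent.reliability,
        "trait_clamp": agent.trait_clamp,
        "slow_horizon": agent.trait_spec.slow_horizon,
        "link": {"omega": dict(agent.link.omega), "gamma0": dict(agent.link.gamma0)},
    }
    return RunResult(records=records, trait_steps=trait_steps, config=config, seed=seed, agent=agent)
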