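"""Synthetic social niche: the data generator every other module runs against.

The niche is a scripted feedback process, not an inferring agent.  On each
trial it emits one of {approval, neutral, rejection} with an approval
probability that mixes an action-dependent term (how well the action suits
the latent norm) and an action-independent base rate, weighted by the
controllability parameter ``kappa``:

    P(approval | action) = kappa * p_approve(action) + (1 - kappa) * base_rate

``kappa = 1`` makes feedback fully contingent on behaviour; ``kappa = 0``
decouples feedback from action entirely, the regime used to probe learned
helplessness.  The remaining probability mass is split between rejection
and neutral by a configurable rejection share.  A regime schedule can
rewrite any parameter at fixed trial indices, which is how favourable,
adverse, shifting and developmental scenarios are scripted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "APPROVAL",
    "NEUTRAL",
    "REJECTION",
    "SCENARIOS",
    "NicheConfig",
    "NicheState",
    "make_niche",
    "outcome_probs",
    "baseline_probs",
    "niche_step",
    "draw_baseline",
    "true_approval_rate",
    "make_scenario",
]

APPROVAL, NEUTRAL, REJECTION = 0, 1, 2

#: Mutable niche parameters a regime-schedule entry may override.
_OVERRIDABLE = {"approval_given_action", "kappa", "base_rate", "rejection_share"}


@dataclass(frozen=True)
class NicheConfig:
    """Parameters of the social feedback process.

    ``approval_given_action`` holds, per action, the approval probability
    when feedback is fully controllable and the action is norm-aligned.
    ``schedule`` is a tuple of ``(trial_index, overrides)`` pairs with
    strictly increasing indices; each takes effect at exactly that trial.
    ``n_outcomes`` is 3 (approval / neutral / rejection) or 2 (approval /
    rejection), the binary reduction.
    """

    approval_given_action: tuple = (0.9, 0.6, 0.15)
    kappa: float = 1.0
    base_rate: float = 0.5
    rejection_share: float = 0.7
    n_outcomes: int = 3
    schedule: tuple = ()
    name: str = "custom"

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.approval_given_action)
        object.__setattr__(self, "approval_given_action", probs)
        for p in probs + (self.kappa, self.base_rate, self.rejection_share):
            if not 0.0 <= p <= 1.0:
                raise ValueError("all niche probabilities must lie in [0, 1]")
        if self.n_outcomes not in (2, 3):
            raise ValueError("n_outcomes must be 2 or 3")
        sched = tuple((int(k), dict(ov)) for k, ov in self.schedule)
        indices = [k for k, _ in sched]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError("schedule trial indices must be strictly increasing")
        for _, ov in sched:
            unknown = set(ov) - _OVERRIDABLE
            if unknown:
                raise ValueError(f"schedule overrides unknown parameters: {sorted(unknown)}")
        object.__setattr__(self, "schedule", sched)

    @property
    def n_actions(self) -> int:
        return len(self.approval_given_action)

    def to_dict(self) -> dict:
        """JSON-native representation (tuples become lists)."""
        def native(v):
            return list(v) if isinstance(v, (tuple, list)) else v

        return {
            "name": self.name,
            "approval_given_action": list(self.approval_given_action),
            "kappa": self.kappa,
            "base_rate": self.base_rate,
            "rejection_share": self.rejection_share,
            "n_outcomes": self.n_outcomes,
            "schedule": [[k, {kk: native(vv) for kk, vv in ov.items()}] for k, ov in self.schedule],
        }


@dataclass
class NicheState:
    """Current niche parameters plus the trial counter."""

    config: NicheConfig
    current: NicheConfig = field(init=False)
    trial: int = 0

    def __post_init__(self) -> None:
        self.current = replace(self.config, schedule=())
        self._apply_schedule()

    def _apply_schedule(self) -> None:
        for k, overrides in self.config.schedule:
            if k == self.trial:
                ov = dict(overrides)
                if "approval_given_action" in ov:
                    ov["approval_given_action"] = tuple(ov["approval_given_action"])
                self.current = replace(self.current, **ov)

    def advance(self) -> None:
        self.trial += 1
        self._apply_schedule()


def make_niche(config: NicheConfig) -> NicheState:
    return NicheState(config=config)


def _split(p_approve: float, cfg: NicheConfig) -> np.ndarray:
    rest = 1.0 - p_approve
    if cfg.n_outcomes == 2:
        return np.array([p_approve, rest])
    return np.array([p_approve, (1.0 - cfg.rejection_share) * rest, cfg.rejection_share * rest])


def outcome_probs(state: NicheState, action: int) -> np.ndarray:
    """Feedback distribution for ``action`` under the current regime."""
    cfg = state.current
    if not 0 <= action < cfg.n_actions:
        raise ValueError(f"action {action} out of range for {cfg.n_actions} actions")
    p = cfg.kappa * cfg.approval_given_action[action] + (1.0 - cfg.kappa) * cfg.base_rate
    return _split(p, cfg)


def baseline_probs(state: NicheState) -> np.ndarray:
    """Action-independent feedback distribution (the ``kappa = 0`` slice)."""
    return _split(state.current.base_rate, state.current)


def niche_step(state: NicheState, action: int, rng: np.random.Generator):
    """Draw one feedback outcome for ``action``, then advance the trial counter.

    Any regime shift scheduled for the next trial index is applied as part
    of advancing, so it is in force for exactly that trial.  Returns
    ``(state, outcome_index)``; the state is updated in place.
    """
    probs = outcome_probs(state, action)
    outcome = int(rng.choice(len(probs), p=probs))
    state.advance()
    return state, outcome


def draw_baseline(state: NicheState, rng: np.random.Generator) -> int:
    """Draw an action-independent observation without advancing the trial."""
    probs = baseline_probs(state)
    return int(rng.choice(len(probs), p=probs))


def true_approval_rate(state: NicheState) -> float:
    """The regime's approval level: mean over actions, mixed with the base rate.

    An action-independent summary of how approving the niche currently is,
    used as the ground truth the agent's self-image belief should track.
    """
    cfg = state.current
    mean_pa = float(np.mean(cfg.approval_given_action))
    return cfg.kappa * mean_pa + (1.0 - cfg.kappa) * cfg.base_rate


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

_FAVOURABLE = dict(approval_given_action=(0.9, 0.6, 0.15), kappa=1.0, base_rate=0.5)
_ADVERSE = dict(approval_given_action=(0.3, 0.15, 0.05), kappa=1.0, base_rate=0.15)
_LOW_EPOCH = dict(approval_given_action=(0.1, 0.08, 0.05), base_rate=0.1)
_HIGH_EPOCH = dict(approval_given_action=(0.9, 0.6, 0.15), base_rate=0.5)

SCENARIOS = ("favorable", "adverse", "uncontrollable", "shifting", "developmental")


def make_scenario(name: str, **overrides) -> NicheConfig:
    """A fully specified niche configuration for a named scenario.

    - ``favorable``: controllable, engaging is usually approved.
    - ``adverse``: controllable but stingy; approval is rare everywhere.
    - ``uncontrollable``: adverse rates with ``kappa = 0`` — feedback no
      longer depends on the agent's action (the helplessness probe).
    - ``shifting``: approval level flips between high and low every 100
      trials (regime changes at trials 100, 200 and 300).
    - ``developmental``: alternating high/low epochs of 60 trials, a
      stylised sequence of life stages.

    Keyword overrides replace any config field after the preset is built.
    """
    if name == "favorable":
        base = dict(_FAVOURABLE)
    elif name == "adverse":
        base = dict(_ADVERSE)
    elif name == "uncontrollable":
        base = dict(_ADVERSE, kappa=0.0)
    elif name == "shifting":
        base = dict(
            _FAVOURABLE,
            schedule=(
                (100, dict(_LOW_EPOCH)),
                (200, dict(_HIGH_EPOCH)),
                (300, dict(_LOW_EPOCH)),
            ),
        )
    elif name == "developmental":
        base = dict(
            _FAVOURABLE,
            schedule=tuple(
                (60 * (i + 1), dict(_LOW_EPOCH if i % 2 == 0 else _HIGH_EPOCH))
                for i in range(6)
            ),
        )
    else:
        raise ValueError(f"unknown scenario {name!r}; valid names: {', '.join(SCENARIOS)}")
    base["name"] = name
    base.update(overrides)
    return NicheConfig(**base)
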