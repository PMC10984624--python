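"""Config-file schemas and loaders (JSON or YAML), validated with pydantic.

Two document kinds are supported: a *model* document that spells out one
generative level's arrays directly (``A``, ``B``, ``C``, ``D``, ``E``,
``horizon``, ...), and an *agent* document with ``state_level``,
``trait_level``, ``trait_link``, ``learning`` and ``niche`` sections that
builds a full hierarchical agent.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .engine import (
    GenerativeModel,
    LikelihoodModel,
    PreferenceVector,
    TransitionModel,
    enumerate_policies,
)
from .esteem import (
    TRAITS,
    HierarchicalAgent,
    LearningConfig,
    StateLevelSpec,
    TraitLevelSpec,
    TraitLink,
)
from .niche import NicheConfig, make_scenario

__all__ = [
    "ModelDocument",
    "AgentDocument",
    "load_document",
    "load_model",
    "load_agent",
    "build_niche_config",
]


def _load_raw(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return data


class ModelDocument(BaseModel):
    """A single-level generative model spelled out as nested lists (row-major)."""

    model_config = ConfigDict(extra="forbid")

    A: list
    B: list
    C: list
    D: list
    E: list | None = None
    horizon: int = Field(ge=1)
    beta0: float = Field(default=1.0, gt=0)
    actions: list[str] | None = None
    labels: dict = Field(default_factory=dict)

    @field_validator("A", "B", "C", "D")
    @classmethod
    def _finite(cls, v):
        arr = np.asarray(v, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("array contains non-finite entries")
        return v

    def build(self) -> GenerativeModel:
        A = np.asarray(self.A, dtype=float)
        B = np.asarray(self.B, dtype=float)
        if B.ndim == 2:
            B = B[:, :, None]
        elif B.ndim == 3:
            # documents list B as [action][s'][s]; the engine wants (s', s, action)
            B = np.moveaxis(B, 0, 2)
        C = np.asarray(self.C, dtype=float)
        D = np.asarray(self.D, dtype=float)
        policies = enumerate_policies(B.shape[2], self.horizon)
        E = (np.full(len(policies), 1.0 / len(policies)) if self.E is None
             else np.asarray(self.E, dtype=float))
        labels = dict(self.labels)
        if self.actions:
            labels["actions"] = list(self.actions)
        return GenerativeModel(
            A=LikelihoodModel(A), B=TransitionModel(B), C=PreferenceVector(C),
            D=D, E=E, policies=policies, horizon=self.horizon, beta0=self.beta0,
            labels=labels,
        )


class StateLevelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    collapse_ideal: bool = False
    self_image_levels: int = Field(default=3, ge=2)
    n_feedback: int = 3
    drift: list[float] = Field(default=[0.6, 0.3, -0.5])
    preference_strength: float = 3.0
    horizon: int = Field(default=2, ge=2)
    reliability: float = Field(default=0.9, ge=0.5, le=1.0)


class TraitLevelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    slow_horizon: int = Field(default=10, ge=1)
    likelihood_dominance: float = Field(default=0.6, ge=1 / 3, le=1.0)
    trait_stickiness: float = Field(default=0.95, ge=0.0, le=1.0)
    valence_stickiness: float = Field(default=0.5, ge=0.0, le=1.0)


class TraitLinkSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    omega: dict[str, float] = Field(default={"low": 0.5, "medium": 1.0, "high": 2.0})
    gamma0: dict[str, float] = Field(default={"low": 0.5, "medium": 1.0, "high": 2.0})
    e_tilt: dict[str, list[float]] | None = None

    @model_validator(mode="after")
    def _check_traits(self):
        for name, mapping in (("omega", self.omega), ("gamma0", self.gamma0)):
            if set(mapping) != set(TRAITS):
                raise ValueError(f"{name} must name exactly the trait levels {TRAITS}")
        return self


class LearningSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    learn_a: bool = False
    learn_b: bool = True
    learn_d: bool = False
    learn_e: bool = False
    learning_rate: float = Field(default=1.0, gt=0)
    concentration: float = Field(default=20.0, gt=0)
    upper_concentration: float = Field(default=10.0, gt=0)
    memory: float = Field(default=0.9, ge=0.0, le=1.0)
    ac_deadband: float = Field(default=0.01, ge=0.0)


class NicheSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    scenario: str | None = None
    approval_given_action: list[float] | None = None
    kappa: float | None = None
    base_rate: float | None = None
    rejection_share: float | None = None
    n_outcomes: int | None = None
    schedule: list | None = None


class AgentDocument(BaseModel):
    """A full hierarchical-agent configuration with an embedded niche."""

    model_config = ConfigDict(extra="forbid")

    state_level: StateLevelSection = Field(default_factory=StateLevelSection)
    trait_level: TraitLevelSection = Field(default_factory=TraitLevelSection)
    trait_link: TraitLinkSection = Field(default_factory=TraitLinkSection)
    learning: LearningSection = Field(default_factory=LearningSection)
    niche: NicheSection = Field(default_factory=NicheSection)
    trait_clamp: str | None = None

    def build_agent(self) -> HierarchicalAgent:
        sl = self.state_level
        spec = StateLevelSpec(
            collapse_ideal=sl.collapse_ideal,
            self_image_levels=sl.self_image_levels,
            n_feedback=sl.n_feedback,
            drift=tuple(sl.drift),
            preference_strength=sl.preference_strength,
            horizon=sl.horizon,
        )
        trait = TraitLevelSpec(**self.trait_level.model_dump())
        link = TraitLink(omega=dict(self.trait_link.omega),
                         gamma0=dict(self.trait_link.gamma0),
                         e_tilt=self.trait_link.e_tilt)
        learning = LearningConfig(**self.learning.model_dump())
        return HierarchicalAgent.build(
            spec, trait, link, learning,
            reliability=sl.reliability, trait_clamp=self.trait_clamp,
        )

    def build_niche(self) -> NicheConfig:
        return build_niche_config(self.niche)


def build_niche_config(section: NicheSection) -> NicheConfig:
    overrides = {
        k: v for k, v in section.model_dump().items()
        if k != "scenario" and v is not None
    }
    if "approval_given_action" in overrides:
        overrides["approval_given_action"] = tuple(overrides["approval_given_action"])
    if "schedule" in overrides:
        overrides["schedule"] = tuple((int(k), dict(ov)) for k, ov in overrides["schedule"])
    if section.scenario is not None:
        return make_scenario(section.scenario, **overrides)
    return NicheConfig(**overrides)


def load_document(path) -> ModelDocument | AgentDocument:
    """Load and validate a config file, dispatching on its keys."""
    data = _load_raw(path)
    if "A" in data:
        return ModelDocument.model_validate(data)
    return AgentDocument.model_validate(data)


def load_model(path) -> GenerativeModel:
    doc = load_document(path)
    if not isinstance(doc, ModelDocument):
        raise ValueError(f"{path} is an agent document, not a model document")
    return doc.build()


def load_agent(path):
    """Returns ``(HierarchicalAgent, NicheConfig)`` from an agent document."""
    doc = load_document(path)
    if not isinstance(doc, AgentDocument):
        raise ValueError(f"{path} is a model document, not an agent document")
    return doc.build_agent(), doc.build_niche()
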