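"""Scenario experiments: the model's qualitative predictions, made runnable.

Each experiment runs the hierarchical agent across seeds and conditions and
reports per-seed metrics together with explicit checks.  Checks are either
*direction* checks (qualitative predictions of the theory: orderings and
signs) or *threshold* checks (magnitudes chosen for this artifact); every
check records which kind it is.  Across-seed consistency is reported as
sign-consistency counts, not p-values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import niche as nm
from .esteem import (
    ACTIONS,
    TRAITS,
    HierarchicalAgent,
    StateLevelSpec,
    TraitLink,
    run_agent,
)

__all__ = [
    "ExperimentReport",
    "config_digest",
    "exp_trait_development",
    "exp_volatility",
    "exp_helplessness",
    "exp_anxiety_buffer",
    "exp_sociometer_tracking",
    "EXPERIMENTS",
]

#: Default problem sizes: enough trials for the slow level to settle and
#: enough seeds for stable sign-consistency counts.
N_TRIALS = 400
N_SEEDS = 20

#: A five-trial total-rejection window used as the standard social stressor.
SHOCK = dict(approval_given_action=(0.0, 0.0, 0.0), base_rate=0.0, rejection_share=1.0)


def config_digest(config: dict) -> str:
    """Stable hex digest of a configuration dict (field order irrelevant)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ExperimentReport:
    """Per-seed metric table plus labelled property checks."""

    name: str
    config: dict
    seeds: list
    metrics: pd.DataFrame
    checks: list = field(default_factory=list)
    degenerate: bool = False

    @property
    def config_digest(self) -> str:
        return config_digest(self.config)

    @property
    def passed(self) -> bool:
        return not self.degenerate and all(c["passed"] for c in self.checks)

    def add_check(self, name: str, kind: str, passed: bool, detail: str = "") -> None:
        if kind not in ("direction", "threshold"):
            raise ValueError("check kind must be 'direction' or 'threshold'")
        self.checks.append({"name": name, "kind": kind, "passed": bool(passed), "detail": detail})

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "config_digest": self.config_digest,
            "config": self.config,
            "seeds": list(self.seeds),
            "degenerate": self.degenerate,
            "checks": self.checks,
            "metrics": self.metrics.to_dict(orient="records"),
        }

    def summary(self) -> str:
        lines = [f"experiment: {self.name} (digest {self.config_digest})"]
        if self.degenerate:
            lines.append("  degenerate run: no metrics")
            return "\n".join(lines)
        for c in self.checks:
            status = "pass" if c["passed"] else "FAIL"
            lines.append(f"  [{c['kind']:9s}] {status}  {c['name']}  {c['detail']}")
        return "\n".join(lines)


def _seed_list(n_seeds: int, base_seed: int) -> list:
    return [int(base_seed + i) for i in range(n_seeds)]


# ---------------------------------------------------------------------------
# Developmental trajectory
# ---------------------------------------------------------------------------


def exp_trait_development(
    n_seeds: int = N_SEEDS,
    epochs: int = 2,
    *,
    trials_per_epoch: int = 200,
    base_seed: int = 0,
) -> ExperimentReport:
    """Early favourable vs early adverse life stages.

    Both arms end in the same mixed environment; the arms differ only in
    the early epochs.  Reports the end-of-run trait posterior per arm; the
    theory predicts the favourable-early arm ends with more belief in high
    trait self-esteem than low, and the adverse-early arm the reverse.
    """
    config = {"experiment": "trait_development", "n_seeds": n_seeds, "epochs": epochs,
              "trials_per_epoch": trials_per_epoch}
    seeds = _seed_list(n_seeds, base_seed)
    if epochs < 1:
        report = ExperimentReport("trait_development", config, seeds, pd.DataFrame(),
                                  degenerate=True)
        return report

    n_trials = epochs * trials_per_epoch
    mixed = dict(approval_given_action=(0.5, 0.4, 0.3), base_rate=0.4, rejection_share=0.7)
    arms = {}
    for arm, early in (("favorable_early", "favorable"), ("adverse_early", "adverse")):
        sched = tuple((trials_per_epoch * (i + 1), dict(mixed)) for i in range(epochs - 1))
        arms[arm] = nm.make_scenario(early, schedule=sched)

    rows = []
    for seed in seeds:
        for arm, cfg in arms.items():
            res = run_agent(HierarchicalAgent.build(), cfg, n_trials, seed=seed)
            post = res.agent.trait_posterior()
            rows.append({"seed": seed, "arm": arm,
                         "p_low": post[0], "p_medium": post[1], "p_high": post[2],
                         "mean_ac": float(res.per_trial("ac").mean())})
    metrics = pd.DataFrame(rows)
    report = ExperimentReport("trait_development", config, seeds, metrics)

    fav = metrics[metrics.arm == "favorable_early"]
    adv = metrics[metrics.arm == "adverse_early"]
    report.add_check(
        "favorable-early: median P(high) > median P(low)", "direction",
        fav.p_high.median() > fav.p_low.median(),
        f"P(high)={fav.p_high.median():.3f} P(low)={fav.p_low.median():.3f}",
    )
    report.add_check(
        "adverse-early: median P(low) > median P(high)", "direction",
        adv.p_low.median() > adv.p_high.median(),
        f"P(low)={adv.p_low.median():.3f} P(high)={adv.p_high.median():.3f}",
    )
    return report


# ---------------------------------------------------------------------------
# Behavioural volatility by trait level
# ---------------------------------------------------------------------------


def exp_volatility(
    n_seeds: int = N_SEEDS,
    *,
    n_trials: int = N_TRIALS,
    base_seed: int = 0,
    min_ordered: int | None = None,
) -> ExperimentReport:
    """Policy-posterior entropy by (clamped) trait level, plus the ablation.

    Each trait level runs against the identical niche and seed; behavioural
    volatility is the mean per-trial policy-posterior entropy (a switch
    rate is reported alongside).  The theory predicts entropy decreases
    with trait level; the ablation arms neutralise the trait link, which
    makes the three arms literally identical, so their entropy differences
    must vanish.
    """
    if min_ordered is None:
        min_ordered = int(np.ceil(0.9 * n_seeds))
    config = {"experiment": "volatility", "n_seeds": n_seeds, "n_trials": n_trials}
    seeds = _seed_list(n_seeds, base_seed)
    cfg = nm.make_scenario("favorable")

    rows = []
    for ablation in (False, True):
        link = TraitLink.neutral() if ablation else TraitLink()
        for seed in seeds:
            for trait in TRAITS:
                agent = HierarchicalAgent.build(link=link, trait_clamp=trait)
                res = run_agent(agent, cfg, n_trials, seed=seed)
                acts = res.actions()
                rows.append({
                    "seed": seed, "trait": trait, "ablation": ablation,
                    "mean_entropy": float(res.per_trial("policy_entropy").mean()),
                    "switch_rate": float(np.mean(acts[1:] != acts[:-1])),
                })
    metrics = pd.DataFrame(rows)
    report = ExperimentReport("volatility", config, seeds, metrics)

    def ordered_count(df) -> int:
        n = 0
        for seed in seeds:
            e = {t: float(df[(df.seed == seed) & (df.trait == t)].mean_entropy.iloc[0])
                 for t in TRAITS}
            n += e["low"] > e["medium"] > e["high"]
        return n

    main = metrics[~metrics.ablation]
    abl = metrics[metrics.ablation]
    n_ordered = ordered_count(main)
    report.add_check(
        f"entropy(low) > entropy(medium) > entropy(high) in >= {min_ordered}/{n_seeds} seeds",
        "direction", n_ordered >= min_ordered, f"ordered in {n_ordered}/{n_seeds}",
    )
    spread = float(abl.groupby("trait").mean_entropy.mean().max()
                   - abl.groupby("trait").mean_entropy.mean().min())
    report.add_check(
        "ablation (trait link neutralised): entropy differences vanish",
        "threshold", spread < 1e-9, f"max spread {spread:.2e}",
    )
    return report


# ---------------------------------------------------------------------------
# Learned helplessness under uncontrollable feedback
# ---------------------------------------------------------------------------


def exp_helplessness(
    n_seeds: int = N_SEEDS,
    *,
    n_trials: int = N_TRIALS,
    base_seed: int = 0,
) -> ExperimentReport:
    """Controllable vs uncontrollable adverse niches.

    Both arms see the same scarce approval; in the uncontrollable arm
    feedback is decoupled from action (kappa = 0).  Reports the
    engage-action frequency over the final third of trials and the mean
    affective charge per arm, plus the shrinking of expected-free-energy
    differences across policies as the uncontrollable arm learns.
    """
    config = {"experiment": "helplessness", "n_seeds": n_seeds, "n_trials": n_trials}
    seeds = _seed_list(n_seeds, base_seed)
    arms = {"controllable": nm.make_scenario("adverse"),
            "uncontrollable": nm.make_scenario("uncontrollable")}
    lo = 2 * n_trials // 3

    rows = []
    for seed in seeds:
        for arm, cfg in arms.items():
            res = run_agent(HierarchicalAgent.build(), cfg, n_trials, seed=seed)
            acts = res.actions()
            g = res.per_trial("efe_selected")
            ent = res.per_trial("policy_entropy")
            rows.append({
                "seed": seed, "arm": arm,
                "engage_final_third": float(np.mean(acts[lo:] == ACTIONS.index("engage"))),
                "mean_ac": float(res.per_trial("ac").mean()),
                "entropy_first_third": float(ent[: n_trials // 3].mean()),
                "entropy_final_third": float(ent[lo:].mean()),
                "efe_selected_mean": float(np.nanmean(g)),
            })
    metrics = pd.DataFrame(rows)
    report = ExperimentReport("helplessness", config, seeds, metrics)

    wide = metrics.pivot(index="seed", columns="arm", values="engage_final_third")
    wins = int((wide["controllable"] > wide["uncontrollable"]).sum())
    report.add_check(
        "engage frequency lower when feedback is uncontrollable (final third)",
        "direction", wins > n_seeds // 2, f"controllable > uncontrollable in {wins}/{n_seeds} seeds",
    )
    unc = metrics[metrics.arm == "uncontrollable"]
    flattens = int((unc.entropy_final_third > unc.entropy_first_third).sum())
    report.add_check(
        "uncontrollable arm: policy beliefs flatten as the action-outcome link unlearns",
        "direction", flattens > n_seeds // 2, f"entropy rises in {flattens}/{n_seeds} seeds",
    )
    return report


# ---------------------------------------------------------------------------
# Anxiety buffering by trait self-esteem
# ---------------------------------------------------------------------------


def exp_anxiety_buffer(
    n_seeds: int = N_SEEDS,
    *,
    pre_trials: int = 80,
    shock_width: int = 5,
    base_seed: int = 0,
) -> ExperimentReport:
    """Identical rejection shock delivered to high- vs low-trait agents.

    Agents live in a favourable niche, then face a ``shock_width``-trial
    window of certain rejection before the niche recovers.  The statistic
    per arm is the largest negative-affective-charge magnitude inside the
    window (zero when the agent never swings negative) and the
    accompanying drop in precision.  The theory predicts high trait
    self-esteem buffers the shock: smaller negative AC and smaller
    precision drop.
    """
    config = {"experiment": "anxiety_buffer", "n_seeds": n_seeds,
              "pre_trials": pre_trials, "shock_width": shock_width}
    seeds = _seed_list(n_seeds, base_seed)
    fav = nm.make_scenario("favorable")
    restore = dict(approval_given_action=fav.approval_given_action,
                   base_rate=fav.base_rate, rejection_share=fav.rejection_share)
    cfg = nm.make_scenario(
        "favorable",
        schedule=((pre_trials, dict(SHOCK)), (pre_trials + shock_width, restore)),
    )
    n_trials = pre_trials + shock_width

    rows = []
    for seed in seeds:
        for trait in ("low", "high"):
            res = run_agent(HierarchicalAgent.build(trait_clamp=trait), cfg, n_trials, seed=seed)
            ac = res.per_trial("ac")[pre_trials:]
            gam = res.per_trial("gamma")
            neg = ac[ac < 0]
            rows.append({
                "seed": seed, "trait": trait,
                "max_neg_ac": float(np.abs(neg).max()) if neg.size else 0.0,
                "min_ac": float(ac.min()),
                "gamma_drop": float(gam[pre_trials - 1] - gam.min()),
            })
    metrics = pd.DataFrame(rows)
    report = ExperimentReport("anxiety_buffer", config, seeds, metrics)

    wide = metrics.pivot(index="seed", columns="trait", values="max_neg_ac")
    wins = int((wide["high"] < wide["low"]).sum())
    report.add_check(
        "post-shock |negative AC| smaller for high-trait agents",
        "direction", wins > n_seeds // 2, f"high < low in {wins}/{n_seeds} seeds",
    )
    return report


# ---------------------------------------------------------------------------
# Sociometer tracking of the niche
# ---------------------------------------------------------------------------


def exp_sociometer_tracking(
    n_seeds: int = N_SEEDS,
    *,
    n_trials: int = N_TRIALS,
    base_seed: int = 0,
    corr_threshold: float = 0.6,
    null_band: float = 0.2,
    burn_in: int = 100,
) -> ExperimentReport:
    """Does the self-image belief track the niche's true approval level?

    Runs the shifting scenario with binary feedback at reliability 0.9
    (informative) and 0.5 (exactly uninformative for two outcomes).
    Reports, per seed, the correlation between the agent's end-of-trial
    belief in the aligned self-image and the regime's action-independent
    approval level, computed after a ``burn_in`` of trials so that the
    initialisation transient (which is common to every seed and would
    correlate with whichever regime happens to come first) is excluded.
    The informative arm should correlate strongly; the uninformative arm
    should show no systematic correlation (the check is on the across-seed
    median, since single-seed correlations between a smooth belief and a
    periodic regime are autocorrelation-inflated).
    """
    config = {"experiment": "sociometer_tracking", "n_seeds": n_seeds, "n_trials": n_trials,
              "corr_threshold": corr_threshold, "null_band": null_band, "burn_in": burn_in}
    seeds = _seed_list(n_seeds, base_seed)
    cfg = nm.make_scenario("shifting", n_outcomes=2)
    if len(cfg.schedule) < 2:
        raise ValueError("tracking requires at least two regime changes")
    spec = StateLevelSpec(n_feedback=2)

    state = nm.make_niche(cfg)
    rates = []
    for _ in range(n_trials):
        rates.append(nm.true_approval_rate(state))
        state.advance()
    rates = np.asarray(rates)

    rows = []
    for seed in seeds:
        for rel in (0.9, 0.5):
            agent = HierarchicalAgent.build(state_spec=spec, reliability=rel)
            res = run_agent(agent, cfg, n_trials, seed=seed)
            belief = res.self_image_alignment()[burn_in:]
            rows.append({"seed": seed, "reliability": rel,
                         "correlation": float(np.corrcoef(belief, rates[burn_in:])[0, 1]),
                         "belief_var": float(belief.var())})
    metrics = pd.DataFrame(rows)
    report = ExperimentReport("sociometer_tracking", config, seeds, metrics)

    informative = metrics[metrics.reliability == 0.9].correlation
    null = metrics[metrics.reliability == 0.5].correlation
    report.add_check(
        f"tracking correlation > {corr_threshold} at reliability 0.9",
        "threshold", informative.median() > corr_threshold,
        f"median r = {informative.median():.3f}",
    )
    report.add_check(
        f"no tracking at reliability 0.5 (|median r| < {null_band})",
        "threshold", abs(null.median()) < null_band, f"median r = {null.median():.3f}",
    )
    return report


EXPERIMENTS = {
    "trait_development": exp_trait_development,
    "volatility": exp_volatility,
    "helplessness": exp_helplessness,
    "anxiety_buffer": exp_anxiety_buffer,
    "sociometer_tracking": exp_sociometer_tracking,
}
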