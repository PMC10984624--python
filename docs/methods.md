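# Methods

This note documents the generative models, the numerical choices, the
synthetic niche, and what the shipped tests and experiments do and do not
establish.

## 1. The single-level engine

Each hierarchical level is a categorical POMDP over a single *joint*
hidden-state index: multi-factor state spaces are flattened before they
reach the engine, and factor structure (reshaping, marginals) lives in the
model builders.  A level is described by

| array | meaning | constraint |
|-------|---------|-----------|
| A (O×S) | P(outcome \| state) | columns categorical |
| B (S×S×U) | P(s′ \| s, action) | columns categorical |
| C (O or O×T) | outcome preferences, log scale (nats) | finite |
| D (S) | initial-state prior | categorical |
| E (P) | habit prior over policies | categorical |

Policies are fixed action sequences with one action per transition: a
trial over timesteps τ = 1..T has T−1 transitions, because the first
observation precedes the first action.  (A length-T policy would carry a
trailing action that can never take effect inside the trial.)

**Perception.**  Per-timestep beliefs are the softmax of three log
messages: past (initial prior / forward through B), future (backward
through Bᵀ), and the current observation's log-likelihood.  The messages
are the *filtered* forward and *likelihood-weighted* backward quantities,
so each observation enters exactly one message and the fixed point
coincides with the exact smoothing posterior of the chain (verified
against exhaustive enumeration to ~1e-16 total variation).  The obvious
alternative — using the smoothed marginals themselves inside both
messages — double-counts evidence; we measured deviations up to total
variation 0.36 from the exact posterior on random two-state models, which
is why it is not used.  Sweeps iterate until the largest belief change
falls below 1e-4 (at most 64 sweeps); non-convergence is flagged on the
result, never fatal.  Timesteps without observations receive the
prior-predictive treatment (no likelihood message).

**Free energy.**  Two evaluators are provided.  `compute_vfe` evaluates
the mean-field form on per-timestep marginals (used inside the agent
loop); its complexity term charges for deviations of the *product* of
marginals from the prior chain, so it is an upper bound that is loose
when the posterior is strongly correlated across time.  `compute_vfe_joint`
evaluates the sequence-level functional on a joint belief array; at the
exact posterior it equals the negative log evidence (tested to 1e-8) and
is the right object for small enumerable models.

**Expected free energy.**  `G(π,τ) = o·(ln o − ln c) + s·H` with
`o = A s`, `H` the per-state outcome entropy, and `c` the
softmax-*normalised* preference distribution.  Normalising C makes the
preference-matched case score exactly zero and costs nothing otherwise:
an unnormalised C shifts every policy's G by the same constant, which the
policy softmax ignores.  A term-by-term double-sum evaluator
(`validation.efe_direct`) serves as the independent cross-check; the two
agree to 1e-8 across the random suite.

**Numerical floors.**  Every logarithm is `ln(x + 1e-16)`; preferences are
stored in log space so "never" outcomes are floored at about −36.8 nats.
Argmax ties break toward the lowest index; every stochastic draw takes an
explicit generator.

**Learning.**  Dirichlet concentrations shadow A, B, D and E.  Counting
rules: observed outcome ⊗ state belief into `a`; belief(τ+1) ⊗ belief(τ)
into the taken action's slice of `b`; the first belief into `d`; the
policy posterior into `e` (off by default — the habit prior is part of the
model specification, and no update rule for it is part of the theory).
Expected models are normalised concentration means (posterior means), not
digamma geometric means: the mean matches the counting interpretation and
keeps the recovery tests exact; the digamma variant would only matter for
very small counts.

## 2. Affective charge and precision

`AC = (π_prior − π_posterior) · G`, with the prior taken before any
observation of the trial (F = 0) and the posterior after feedback.  The
sign convention is fixed by the requirement that positive AC mean "belief
moved toward low expected free energy".  Precision follows as a one-shot
assignment `β̄ = max(β₀ − AC, 0.05)`, `γ = 1/β̄`: good news sharpens policy
selection, bad news loosens it, and the clamp keeps γ finite.  β̄ does not
relax toward β₀ between trials (no forgetting); each trial's update
starts from β₀ again, so γ stays within an AC-sized neighbourhood of the
trait-set baseline.  Valence labels use a deadband (default 0.01 nats in
the agent loop; 0 in the raw function).

## 3. The two-level self-esteem model

**Fast level.**  Hidden factors: three binary ideal-image components
(competence, social conformity, physical attractiveness; a config switch
collapses them to one 3-level factor) × a K=3-level self-image
(misaligned / partial / aligned).  Joint size 24 (collapsed: 9).  An
alignment score in [0,1] averages the ideal components met with the
self-image level; the likelihood maps each state's score to the nearest
feedback anchor (approval=1, neutral=0.5, rejection=0) with probability
`reliability`, spreading the rest evenly.  Reliability 1 gives
deterministic columns; with the binary feedback reduction, reliability
0.5 is exactly uninformative.  Transitions: the ideal image is static
within a trial; the self-image moves one level toward alignment with
probability 0.6 under *engage* and 0.3 under *conform*, and one level away
with probability 0.5 under *withdraw* (ends absorb).  These drifts are the
agent's *model*, and with transition learning on they are reshaped by
experience.  Preferences: +3 / 0 / −3 nats for approval / neutral /
rejection — rejection strongly dispreferred is what makes social threat
aversive and drives the avoidance phenomena.  Trials have horizon 2
(observe, act, observe feedback); one decision cycle per trial.

**Slow level.**  Trait {low, medium, high} × valence {negative, neutral,
positive}, 9 joint states; observations are trial summaries (dominant
valence label × final self-image bin, 9 symbols).  The likelihood starts
weakly informative (diagonal dominance 0.6 on each axis, e.g. high trait
↔ top self-image bin) and is refined by Dirichlet counts.  Transitions
are sticky: 0.95 for trait (slow), 0.5 for valence (labile).  The level
is perception-and-learning only — it has a single do-nothing policy,
because the theory gives the upper level no actions; its influence is
entirely top-down through the priors it sets.  After each trait step the
propagated posterior becomes the next block's empirical prior, which is
what gives trait its attractor-like persistence (hysteresis).

**Trait link.**  The MAP trait sets, for the next block of trials:
`ω` — the exponent applied to the lower B's columns
(`normalise(c^ω)`; identity at 1, sharper above, flatter below), and
`γ₀` — the prior policy precision (β₀ = 1/γ₀).  Defaults:

| trait | ω | γ₀ |
|-------|----|----|
| low | 0.5 | 0.5 |
| medium | 1.0 | 1.0 |
| high | 2.0 | 2.0 |

Both components express the same idea — confidence in the self-model —
on the state-transition and policy-selection sides respectively.  Both
are needed: the volatility ordering is carried mostly by ω, while the
anxiety-buffering direction (smaller negative AC after a rejection shock
for high-trait agents) specifically requires γ₀ to rise with trait.
Sharper B alone *amplifies* shock responses, because it inflates both the
G spread and the evidence shift; it is the saturated, high-γ policy prior
(further raised by the positive AC accrued beforehand) that absorbs the
shock.  Consequently the volatility *ablation* neutralises the whole
link (ω ≡ 1 and γ₀ ≡ 1): neutralising only ω would leave the γ₀ channel
ordering the arms.  With the link neutral the three arms are literally
identical runs, so the ablation's "noise band" is numerical zero.  An
optional per-trait habit tilt (`e_tilt`) exists and is off by default.

**Agent loop.**  Per trial: baseline observation (action-independent),
per-policy inference and F, per-policy G, policy prior (F=0) and decision
posterior under the current γ, action sampling from the first-action
marginal, niche feedback, re-inference, post-feedback posterior, AC,
precision update, Dirichlet counting with the policy-averaged beliefs,
and a leaky carry-over of the final state belief into the next trial's
D (`0.9·belief + 0.1·uniform`) — the self-image persists across trials
but slowly forgets.  Learning defaults: B on (concentration 20 — the
prior resists roughly the first tens of trials), A/D/E off at the fast
level; the slow level learns its likelihood and initial-state counts
(concentration 10).  The loop deep-copies the agent, so reruns with the
same seed are bit-identical.

## 4. The synthetic niche

`P(approval|u) = κ·p(u) + (1−κ)·base`; the non-approval mass splits
rejection:neutral = 0.7:0.3 by default (the alphabet itself is a design
choice: approval/neutral/rejection, with a binary reduction available).
Scenario presets (all probabilities are package choices, documented in
`make_scenario`): *favorable* (engage approved 0.9, κ=1), *adverse*
(0.3/0.15/0.05, base 0.15), *uncontrollable* (adverse with κ=0),
*shifting* (high/low flips at trials 100/200/300), *developmental*
(60-trial alternating epochs).  Regime overrides apply at exactly the
scheduled trial index.  The niche is scripted — it does not infer; group
dynamics exist in this artifact only through these feedback statistics,
and multi-agent interaction is out of scope.

What the niche does *not* emulate about real social data: observer-
dependent feedback semantics, nonstationarity beyond scheduled shifts,
heterogeneous audiences, and any coupling from the agent's state back to
the niche's norms.  Passing tests therefore show internal coherence of
the model and its predicted directions under controlled feedback
statistics — not calibration to human data.

## 5. Experiments and statistics

Problem sizes (package choices): 400 trials, slow horizon 10, 20 seeds
per arm; the buffering experiment uses 80 pre-trials plus a 5-trial
total-rejection window, and trait development uses two 200-trial epochs.
Direction checks (orderings/signs predicted by the theory) are reported
as sign-consistency counts across seeds, never p-values; threshold checks
(magnitudes chosen for this artifact) are labelled as such in every
report.  Two statistics deserve a note:

- *Tracking* correlates the end-of-trial aligned-self-image belief with
  the regime's action-independent approval level
  (`κ·mean_u p(u) + (1−κ)·base`), after a 100-trial burn-in.  The
  action-independent ground truth prevents the null arm from picking up
  correlation through the agent's own actions, and the burn-in removes
  the initialisation transient (uniform random actions have net-positive
  self-image drift, which would correlate with whichever regime comes
  first in every seed identically).  The null check is on the across-seed
  median because single-seed correlations between a smoothed belief and
  a periodic regime are autocorrelation-inflated in both directions.
- *Buffering* scores each arm by the largest negative-AC magnitude inside
  the shock window (zero if AC never goes negative — a confident agent
  can re-interpret a single rejection as likelihood noise).

**Dirichlet recovery** is demonstrated in the fully observable regime
(deterministic likelihood), where counting over inferred beliefs is
consistent and the expected model matches the empirical frequencies of
the simulated data up to the prior's pseudocounts.  With ambiguous
likelihoods, counting over beliefs is biased (the classic
counting-vs-EM gap); the package makes no claim of consistency there.

## 6. Known limitations

- Mean-field F on marginals is loose for strongly correlated posteriors;
  quantities that need tightness should use the joint evaluator.
- One decision cycle per trial (horizon 2) keeps the policy space tiny;
  longer horizons are supported by the engine but the esteem builders
  ship only whole-trial action commitments.
- The upper level never acts; meta-cognitive *control* (beyond
  precision-setting) is not modelled.
- Trait enters only through ω, γ₀ and the optional habit tilt; preference
  precision modulation is deliberately left as a hook (off by default).
- Self-esteem is modelled domain-generally; domain-specific esteem would
  need per-context ideal-image factors and is out of scope.
- All magnitudes are simulation-scale choices; nothing is fitted to
  human questionnaire or behavioural data.
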