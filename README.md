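# sociometer

Self-esteem as an inferential *sociometer*: an agent's running estimate of
how well it is doing in its social niche.  This package implements that
idea as a runnable active-inference simulation for computational
psychiatry and cognitive-modelling work: a generic discrete-state active
inference engine, affective-charge / precision dynamics, and a two-level
generative model in which slow **trait** self-esteem modulates fast
**state**-level inference about social feedback — all exercised against a
fully synthetic, scripted social environment.  No empirical data is
required or used.

## The model in brief

The agent is a categorical POMDP with likelihood **A** (P(o|s)),
action-conditioned transitions **B**, log-preferences **C**, initial prior
**D** and habit prior **E** over policies π (action sequences).

- **Perception** minimises variational free energy
  `F = D_KL[Q(s)‖P(s|π)] − E_Q[ln P(o|s)]` (complexity − accuracy);
  per-policy state beliefs are computed by message passing whose fixed
  point is the exact smoothing posterior of the chain.
- **Planning** scores each policy by expected free energy per future step
  `G(π,τ) = (A s) · (ln A s − ln C) + s · H` — risk (divergence of
  predicted outcomes from preferences) plus ambiguity (expected outcome
  entropy H).
- **Decision** samples from `Q(π) = σ(ln E − F − γ G)`, where the
  precision γ = 1/β̄ sets how deterministically the agent follows G.
- **Affect**: after feedback arrives, the affective charge
  `AC = (π_prior − π_posterior) · G` is positive exactly when beliefs
  shifted toward lower-G policies (things went better than expected); it
  updates precision via `β̄ = max(β₀ − AC, β_min)` and its sign is the
  trial's valence.
- **Learning**: Dirichlet concentration parameters shadow A, B, D and E
  and accumulate evidence by counting.

On top of this sits the self-esteem hierarchy.  The fast level infers a
joint hidden state — an *ideal image* (competence, social conformity,
physical attractiveness) and a *self-image* (alignment with that ideal) —
from social feedback {approval, neutral, rejection}, and chooses between
*engage*, *conform* and *withdraw*.  Every `slow_horizon` trials the AC
trace and the final self-image posterior are discretised into an
observation for the slow level, which infers trait self-esteem
{low, medium, high} crossed with core valence.  The inferred trait feeds
back down as empirical priors: it exponentiates the columns of the lower
B (precision modulation ω), sets the prior policy precision γ₀, and can
tilt habits.  High trait therefore means sharp expectations and committed
behaviour; low trait means flat expectations and volatile behaviour.

The synthetic niche emits feedback with
`P(approval|u) = κ·p(u) + (1−κ)·base`, where the controllability κ can
decouple feedback from action entirely (the learned-helplessness probe),
and a regime schedule scripts favourable/adverse/shifting/developmental
scenarios.

## Worked example

```
$ python examples/run_favorable.py
200 trials in the favourable niche (engage is usually approved)
  engage    chosen 72.5% of trials
  conform   chosen 22.5% of trials
  withdraw  chosen 5.0% of trials
mean affective charge: +0.055 nats (positive: outcomes kept beating expectations)
policy precision gamma rose from 1.07 to 2.42 (mean, last 50)
final trait posterior: P(low)=0.02, P(medium)=0.02, P(high)=0.96
consistent approval accumulated into a stable high-trait empirical prior
```

The agent seeks the approval it prefers (engage dominates), its affective
charge runs positive because approving feedback keeps shifting policy
beliefs toward low-expected-free-energy policies, the positive charge
raises γ (more confident action selection), and two hundred trials of
summaries accumulate into a trait posterior concentrated on "high".

Other examples, one per capability: `engine_basics.py` (inference vs
exhaustive enumeration on a toy model), `volatility_by_trait.py`,
`helplessness.py`, `sociometer_tracking.py`.

There is also a thin CLI:

```
sociometer run favorable --seed 0 --trials 400 --out runs/fav
sociometer experiment volatility --seeds 20 --out runs/vol
sociometer validate-config my_agent.yaml
```

`experiment` exits non-zero if any property check fails; runs are written
as a JSONL trajectory plus CSV/JSON summaries with a config digest.

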