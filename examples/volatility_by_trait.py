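"""Behavioural volatility as a function of trait self-esteem.

Clamps the trait level (low / medium / high) and runs each agent against
the identical niche and seeds.  Higher trait sharpens the transition model
and the prior policy precision, so action selection becomes more
deterministic; the printed entropy of the policy posterior is the
volatility measure.
"""

from sociometer.experiments import exp_volatility

report = exp_volatility(n_seeds=5, n_trials=150)
table = report.metrics[~report.metrics.ablation].groupby("trait")[
    ["mean_entropy", "switch_rate"]
].mean().reindex(["low", "medium", "high"])

print(table.round(3))
print()
print(report.summary())
print("entropy (nats) falls from low to high trait: confident agents commit;")
print("the ablation rows neutralise the trait link, erasing the differences.")
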