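"""Learned helplessness under uncontrollable feedback.

Two adverse niches deliver equally scarce approval; in one of them the
feedback is decoupled from the agent's action (controllability kappa = 0).
When acting stops mattering, the learned action-outcome model flattens and
the agent stops engaging.
"""

from sociometer.experiments import exp_helplessness

report = exp_helplessness(n_seeds=5, n_trials=300)
table = report.metrics.groupby("arm")[
    ["engage_final_third", "mean_ac", "entropy_final_third"]
].mean()

print(table.round(3))
print()
print(report.summary())
print("engage frequency in the final third is lower in the uncontrollable arm:")
print("with no action-outcome contingency left to exploit, the agent disengages.")
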