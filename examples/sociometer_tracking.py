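"""The sociometer at work: self-image beliefs track social approval.

A shifting niche flips its approval level every 100 trials.  With reliable
feedback the agent's belief that its self-image is aligned with the ideal
rises and falls with the niche's true approval rate; with uninformative
feedback the belief decouples from it.
"""

from sociometer.experiments import exp_sociometer_tracking

report = exp_sociometer_tracking(n_seeds=5)
table = report.metrics.groupby("reliability")[["correlation", "belief_var"]].median()

print(table.round(3))
print()
print(report.summary())
print("correlation is computed per seed between the end-of-trial aligned-self-image")
print("belief and the regime's approval level; reliability 0.5 is the no-signal null.")
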