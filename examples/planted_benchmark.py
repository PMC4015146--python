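"""Leave-one-out benchmark on a synthetic graph with planted associations.

Generates a three-domain global graph with 10 planted query-target pairs,
hides each direct arc in turn and asks the prioritizer to recover the true
target, then repeats with shuffled labels as a null control.
"""

from netprio import (
    FixtureSpec,
    PropagationParams,
    generate_hetnet,
    run_loo,
    shuffle_labels,
)

spec = FixtureSpec(planted_pairs=10, seed=42)
graph, pairs = generate_hetnet(spec)
params = PropagationParams(gamma=0.1)

report = run_loo(graph, pairs, params)
print("planted-association benchmark (arc hidden per trial)")
print(report.summary())

shuffled = shuffle_labels(graph, pairs, seed=43)
control = run_loo(graph, shuffled, params, remove_arcs=False)
print("\nlabel-shuffled null control")
print(control.summary())

print(
    "\nAn AUC near 1 on the planted pairs and near 0.5 on the shuffled "
    "control\nshows the ranking responds to genuine propagated signal, "
    "not to network\nstructure alone."
)
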