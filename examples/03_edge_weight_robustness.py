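"""Edge-weight robustness: are the simulated trends an artifact of the
chosen edge weights?

All edge weights of the toy network are resampled uniformly at random; 100
such runs define a per-node background trend (mean activity per iteration).
50 further groups of 100 equally randomised runs each produce group trends,
and per node the Spearman correlation between group and background trend is
recorded.  Nodes whose correlation distribution sits tightly near 1 have
dynamics driven by the topology and signs, not by the particular weights.
Receptors are excluded: with no incoming edges their trends cannot depend on
weights.
"""

import siglogic as sl

net = sl.toy_network()
schedule = sl.Schedule([
    sl.PerturbationEvent("EGFR", 0.5),
    sl.PerturbationEvent("TNFR", 0.5),
])
config = sl.SimulationConfig(iterations=32, degradation_rate=0.2, seed=11)

result = sl.robustness_analysis(net, schedule, config,
                                n_background=100, n_groups=50, group_size=100)

print("node ranking by median correlation with the background trend:")
for node, med in result.ranked().items():
    vals = result.correlations[node]
    print(f"  {node:>13}  median={med:+.3f}  range=[{vals.min():+.3f}, {vals.max():+.3f}]")

print(
    "\nMedians near 1 with a narrow range mean the node's activity trend "
    "is robust to how strongly each interaction is weighted."
)
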