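"""Simulate a signaling cascade under time-staggered drug perturbations.

The bundled toy network is stimulated in two ways: (1) EGFR and TNFR active
from the start at levels 0.5 and 0.8, and (2) an EGFR inhibitor added at
iteration 10 (level -1, full inhibition) with TNFR stimulated at level 0.8
from iteration 20.  The printed activities show the receptor dropping
sharply once its inhibitor is added, the downstream kinase ERK following
with a delay, and TNFR first decaying from its random initial value and then
jumping to its plateau (the stimulus fixed point A/(A+d) = 0.8/1.0 = 0.8).
"""

import siglogic as sl

net = sl.toy_network()
config = sl.SimulationConfig(iterations=100, degradation_rate=0.2, seed=1)

immediate = sl.Schedule([
    sl.PerturbationEvent("EGFR", 0.5),
    sl.PerturbationEvent("TNFR", 0.8),
])
staggered = sl.Schedule([
    sl.PerturbationEvent("EGFR", -1.0, start=10),
    sl.PerturbationEvent("TNFR", 0.8, start=20),
])

for name, schedule in [("immediate stimulation", immediate),
                       ("staggered drug addition", staggered)]:
    traj = sl.run(net, schedule, config)
    print(f"\n== {name} ==")
    for node in ("EGFR", "TNFR", "ERK"):
        series = traj.for_node(node)
        picks = [0, 5, 10, 15, 20, 25, 50, 100]
        line = "  ".join(f"t={t}:{series[t]:.3f}" for t in picks)
        print(f"{node:>5}  {line}")
    stable = sl.detect_stable_state(traj, tol=1e-4)
    print("stable state reached:", "yes" if stable is not None else "no")

print(
    "\nActivities are in [0, 1] (0 fully inhibited, 1 fully activated).  "
    "Under staggered addition EGFR collapses within a few steps of "
    "iteration 10 and TNFR plateaus at 0.8 right after iteration 20."
)
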