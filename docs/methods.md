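# Methods

## Model and update rule

The simulator iterates a generalized logical model over a directed network
of molecular species. Node activities are continuous in [0, 1]
(0 fully inhibited, 1 fully activated); each edge carries a sign
(activating/inhibiting) and a weight in [0, 1]; the signal transmitted along
an edge is the source activity times the edge weight. All nodes update
synchronously from the complete previous state:

X_t = (1 − d)·X_{t−1} + [1 − Π(1 − A_i)]·Π(1 − B_j)·(1 − X_{t−1})
      − Π(1 − A_i)·[1 − Π(1 − B_j)]·X_{t−1}

with d the global degradation rate, A_i the activating and B_j the
inhibiting incoming signals. The activation term treats incoming activators
as independent chances of activating the inactive fraction, thinned by the
probability Π(1 − B_j) that no inhibitor interferes; the symmetric blocking
term erodes the active fraction. The model is a strict generalization of a
synchronous Boolean network: with d = 0, unit weights and binary states the
rule reduces to "any active activator and no active inhibitor switches the
node on; an active inhibitor alone switches it off; otherwise hold"
(verified exhaustively in the tests for all 2^n states, n ≤ 4).

Key consequences used throughout the package:

* a node receiving a constant activating signal A converges geometrically to
  the fixed point A/(A + d) (contraction factor 1 − d − A, assuming no
  clamping en route);
* a parentless node decays as (1 − d)^t · X_0 — empty products are defined
  as 1, the standard convention, which makes unstimulated receptors decay
  exactly as intended;
* the stable level is independent of the initial state; the initial state
  only sets the transient's length.

### Clamping

The raw rule can leave [0, 1] in extreme regimes (e.g. d = 1 together with
active inhibition drives the update below 0). Since activities are by
definition bounded, every update is clamped to [0, 1] by default; a
`clamp=False` mode applies the rule verbatim for diagnostics. In ordinary
parameter regimes (d well below 1, signals in [0, 1]) clamping never fires.

### Scheduled perturbations

Extracellular inputs are modeled by a virtual node with activity pinned
to 1, upstream of the user-designated input nodes. A perturbation event
(target, level l ∈ [−1, 1], start, optional end; iterations are 1-based)
installs, while active, a virtual edge of weight |l| — activating for l > 0,
inhibiting for l < 0. Because the virtual activity is 1, the delivered
signal equals |l|; level −1 is full inhibition and level 0 delivers nothing.
An inhibiting level between 0 and −1 scales the virtual inhibiting edge
linearly (weight = |l|). Events persist until their end iteration, or
forever if none is given — a drug, once added, is not withdrawn. Overlapping
events for the same target are rejected at schedule construction, so queries
never tie-break. Before an event's start the schedule contributes nothing:
simulating with and without it gives bit-identical prefixes.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `iterations` | — (typ. 32 or 100) | number of synchronous updates; discrete steps approximate continuous time |
| `degradation_rate` d | 0.2 | per-iteration fractional loss of the activated form, dimensionless in [0, 1]; 0.2 gives plateaus within ~10 steps of a stimulus |
| `seed` | none | drives the uniform [0, 1) random initial activities |
| `initial_state` | random | explicit vector or per-node mapping for reproducibility studies |
| `clamp` | on | keep activities in [0, 1] after each update |
| edge weights | — (toy data: 0.7 activation, 0.8 inhibition) | interaction strengths |

Degradation is global; per-node rates would be a straightforward config
extension but nothing in the analyses needs them.

## Analyses

**Stable-state detection** declares a trajectory settled when the largest
per-node change over the last `window` (default 5) transitions is below
`tol` (default 1e-4), and returns the final state; sustained oscillations
return none. The initial-value sweep applies the same criterion to the swept
node's own series (a slow unrelated node elsewhere should not mask the
receptor's convergence) and reports time-to-stability as the first iteration
from which the node stays within 0.01 of its stable level.

**Downsampling and goodness of fit.** To compare an N-iteration trajectory
with T measured time points, the states at iterations N/T, 2N/T, …, N are
extracted (the initial state never participates); N must be divisible by T —
the package refuses to interpolate silently, and mapping simulated steps
onto real time more faithfully than this linear alignment is out of scope.
Goodness of fit is the Spearman rank correlation (scipy, average ranks for
ties) between simulated and measured courses: the model predicts trends, not
absolute abundances. A constant vector makes rank correlation undefined;
the result is then NaN, never a silently imputed 0.

**Edge-weight robustness.** With topology and signs fixed, all edge weights
are resampled (default i.i.d. uniform on [0, 1)) for each run.
`n_background` runs (default 100) define the background trend: the per-node
mean activity at each post-initial iteration. Each of `n_groups` (default
50) groups of `group_size` (default 100) equally randomised runs yields a
group mean trend, and per node the Spearman correlation between group and
background trend is recorded; nodes are ranked by median correlation.
Correlations use all post-initial iterations, not downsampled points. Nodes
without incoming edges are excluded — their dynamics cannot depend on edge
weights. Seeding: the master seed spawns one stream for initial states and
one for weights; initial-state seeds are indexed by run position, so the
k-th run of every group and of the background shares its initial state and
only the weight randomisation distinguishes groups. This makes the
degenerate check exact — with a point-mass weight sampler and
group_size = n_background, every group trend equals the background trend and
all defined correlations are 1 — while keeping group correlations honest
estimates of weight-induced (not initial-state-induced) variation.

**Condition fit report.** A named design maps each input node to a level in
[−1, 1] (applied from iteration 1) or to "random": no virtual edge, a seeded
random initial activity, free evolution — how an unperturbed receptor
behaves. Each condition is simulated, downsampled to the measured T and
correlated per shared protein; proteins measured but absent from the network
are reported as skipped, never fatal.

## Synthetic data

`generate_network` samples exactly `n_edges` distinct ordered node pairs
uniformly without replacement (no self-loops — self-dependence is already in
the (1 − d)·X term, a self-edge would double-count), signs i.i.d. Bernoulli
with activating fraction 0.75 by default (curated signaling maps are
predominantly activating; the fraction is tunable), weights i.i.d. uniform
by default. Input nodes prefer in-degree-0 (receptor-like) nodes before
arbitrary ones. Degree structure is uniform-random, not scale-free. The
benchmark shapes exercised in the tests are 5 nodes / 13 edges and
500 nodes / 6124 edges (the latter simulates 100 iterations in well under a
second on one core; the compiled per-target index arrays make a step a few
vectorised numpy reductions).

`generate_pseudo_measurements` simulates, downsamples to T points (T = 8 by
convention, emulating an 8-time-point phosphoproteomics table), adds i.i.d.
Gaussian noise and truncates at 0. What it emulates: a normalised protein ×
time-point activity table on the simulation's own scale, with independent
per-cell noise. What it does not emulate: biological correlation structure
beyond what the simulator induces, systematic (antibody/batch) biases,
missingness, or real-time/iteration misalignment. Passing the recovery tests
therefore shows the pipeline is self-consistent (noiseless tables are
recovered at correlation exactly 1; the median fit over 20 seeds decays
monotonically through noise SD 0, 0.05, 0.5) — it does not certify accuracy
on real measurements.

A caveat the examples make visible: once trajectories plateau (d = 0.2
settles most nodes within a handful of steps), the downsampled points differ
by very little, so rank-based fit becomes sensitive to even modest noise,
and two conditions whose trends share the same rank ordering (e.g. both
monotone decreasing) score identically however different their levels.

## Numerical and design choices

* Synchronous updates only; asynchronous semantics are deliberately out of
  scope.
* Edge-list dialect: 4 columns "source sign weight target", `#` comments;
  `#!` directive comments (`#! nodes:`, `#! inputs:`) carry node order,
  isolated nodes and input designations so write→read round-trips are exact
  (weights are serialised with full-precision repr). Plain SIF-style readers
  treat directives as comments. One edge per ordered pair; parallel edges
  are rejected.
* All randomness flows through numpy Generators seeded from explicit seeds;
  identical (network, schedule, config) inputs give bit-identical
  trajectories, and every CLI command writes a manifest (parameters, seed,
  input digests, version) sufficient to reproduce its output byte-for-byte.
* Degenerate inputs fail loudly: zero iterations, windows that do not fit
  the trajectory, non-divisible downsampling, out-of-range activities,
  weights or levels, schedules targeting non-input nodes.

## Limitations

* No edge-weight learning from data, no statistical testing on correlation
  differences, no attractor enumeration over all initial states, no
  ODE/stochastic semantics.
* The bundled 14-node toy network is illustrative, hand-drawn for examples
  and tests; it is not a curated pathway reconstruction.
* The iteration↔real-time mapping is a fixed linear alignment via the
  divisibility rule; learned time-warping is future work.
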