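"""Random networks and noisy pseudo-measurements.

Everything downstream of the simulator is testable without any external
dataset: :func:`generate_network` draws random signed, weighted topologies
(the shape classes used for scaling studies, e.g. 5 nodes / 13 edges or
500 nodes / 6124 edges), and :func:`generate_pseudo_measurements` turns a
simulation into a noisy protein x time-point table that stands in for a real
phosphoproteomics time course.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .analysis import MeasuredTimeCourse, downsample
from .network import ACTIVATING, INHIBITING, Edge, SignalingNetwork
from .perturbation import Schedule
from .simulate import SimulationConfig, run

__all__ = ["NetworkSpec", "generate_network", "generate_pseudo_measurements"]


@dataclass(frozen=True)
class NetworkSpec:
    """Shape and randomisation parameters for a generated network.

    ``activating_fraction`` defaults to 0.75: curated signaling maps are
    predominantly activating, with inhibitory edges a minority.  Weights are
    sampled per edge from ``weight_sampler`` (default i.i.d. uniform [0, 1)).
    ``n_inputs`` nodes are designated input nodes, preferring nodes with no
    incoming edges (receptor-like) before falling back to arbitrary nodes.
    """

    n_nodes: int
    n_edges: int
    activating_fraction: float = 0.75
    weight_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None
    n_inputs: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (isinstance(self.n_nodes, int) and self.n_nodes >= 1):
            raise ValueError(f"n_nodes must be a positive integer, got {self.n_nodes!r}")
        max_edges = self.n_nodes * (self.n_nodes - 1)
        if not (isinstance(self.n_edges, int) and 0 <= self.n_edges <= max_edges):
            raise ValueError(
                f"n_edges must lie in [0, {max_edges}] for {self.n_nodes} nodes "
                f"(no self-loops, no duplicate ordered pairs), got {self.n_edges!r}"
            )
        if not 0.0 <= self.activating_fraction <= 1.0:
            raise ValueError(
                f"activating_fraction must lie in [0, 1], got {self.activating_fraction!r}"
            )
        if not (isinstance(self.n_inputs, int) and 0 <= self.n_inputs <= self.n_nodes):
            raise ValueError(
                f"n_inputs must lie in [0, {self.n_nodes}], got {self.n_inputs!r}"
            )


def generate_network(spec: NetworkSpec) -> SignalingNetwork:
    """Draw a random signed, weighted directed network of the given shape.

    Exactly ``spec.n_edges`` distinct ordered node pairs are sampled
    uniformly without replacement (self-loops excluded); each edge is
    activating with probability ``spec.activating_fraction``.  The same spec
    and seed always reproduce the identical network.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    width = len(str(n))
    names = tuple(f"N{i:0{width}d}" for i in range(1, n + 1))

    # ordered pairs (i, j), i != j, encoded as i*(n-1) + j' with j' skipping i
    codes = rng.choice(n * (n - 1), size=spec.n_edges, replace=False)
    sources, rem = np.divmod(codes, n - 1)
    targets = rem + (rem >= sources)

    activating = rng.random(spec.n_edges) < spec.activating_fraction
    sampler = spec.weight_sampler
    if sampler is None:
        weights = rng.uniform(0.0, 1.0, size=spec.n_edges)
    else:
        weights = np.asarray(sampler(rng, spec.n_edges), dtype=float)

    edges = tuple(
        Edge(names[s], names[t], ACTIVATING if a else INHIBITING, float(w))
        for s, t, a, w in zip(sources, targets, activating, weights)
    )

    in_deg = np.zeros(n, dtype=int)
    for t in targets:
        in_deg[t] += 1
    order = sorted(range(n), key=lambda i: (in_deg[i] > 0, i))
    inputs = tuple(names[i] for i in order[: spec.n_inputs])
    return SignalingNetwork(names, edges, inputs)


def generate_pseudo_measurements(
    net: SignalingNetwork,
    schedule: Schedule | None,
    config: SimulationConfig,
    n_points: int,
    noise_sd: float,
    seed: int | None = None,
) -> MeasuredTimeCourse:
    """Simulate, downsample and corrupt with noise to emulate a measured
    protein x time-point table.

    i.i.d. Gaussian noise of standard deviation ``noise_sd`` is added to
    every downsampled activity and the result truncated at 0 (measured
    abundances are nonnegative).  With ``noise_sd = 0`` the table is exactly
    the downsampled simulation, so the fit machinery must recover Spearman
    correlation 1 for every protein with a non-constant trend.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be nonnegative, got {noise_sd!r}")
    traj = run(net, schedule, config)
    sim = downsample(traj, n_points)
    rng = np.random.default_rng(seed)
    noisy = sim.to_numpy() + rng.normal(0.0, noise_sd, size=sim.shape)
    np.maximum(noisy, 0.0, out=noisy)
    return MeasuredTimeCourse(
        proteins=tuple(sim.index),
        time_points=tuple(int(c) for c in sim.columns),
        values=noisy,
    )
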