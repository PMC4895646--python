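"""Synchronous discrete-time simulation of the generalized logical model.

Each node carries a continuous activity level in [0, 1] (0 fully inhibited,
1 fully activated).  At every iteration all nodes are updated together from
the complete previous state:

    X_t = (1 - d) * X_{t-1}
          + [1 - prod_i(1 - A_i)] * prod_j(1 - B_j) * (1 - X_{t-1})
          - prod_i(1 - A_i) * [1 - prod_j(1 - B_j)] * X_{t-1}

where ``d`` is the degradation rate of the activated form, ``A_i`` (``B_j``)
is the signal — parent activity times edge weight — from the i-th activating
(j-th inhibiting) parent, and empty products equal 1, so a parentless node
decays geometrically as ``(1 - d) X_{t-1}``.  ``1 - prod(1 - A_i)`` is the
joint activating effect on the inactive fraction, ``prod(1 - B_j)`` the
probability that no inhibiting signal blocks it; the symmetric blocking term
acts on the active fraction.

The rule can leave [0, 1] in extreme regimes (e.g. ``d = 1`` with active
inhibition), so by default each update is clamped back to [0, 1]; raw mode is
available for diagnostics.  Scheduled perturbations enter as virtual edges
among the parents of input nodes (see :mod:`siglogic.perturbation`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import ACTIVATING, SignalingNetwork
from .perturbation import Schedule

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "CompiledNetwork",
    "update_node",
    "step",
    "run",
    "detect_stable_state",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for one simulation run.

    Parameters
    ----------
    iterations
        Number of synchronous updates (columns 1..iterations of the
        trajectory; column 0 is the initial state).
    degradation_rate
        Per-iteration fractional loss ``d`` of the activated form, in [0, 1].
    seed
        Seed for the random initial state (ignored if ``initial_state`` is
        given).
    initial_state
        ``None`` to draw i.i.d. uniform [0, 1) initial activities from
        ``seed``, or an explicit vector/mapping of node activities.
    clamp
        Clamp every updated activity back into [0, 1] (default); with
        ``clamp=False`` the rule is applied verbatim.
    """

    iterations: int
    degradation_rate: float = 0.2
    seed: int | None = None
    initial_state: Sequence[float] | Mapping[str, float] | None = None
    clamp: bool = True

    def __post_init__(self) -> None:
        if not (isinstance(self.iterations, int) and self.iterations >= 1):
            raise ValueError(f"iterations must be an integer >= 1, got {self.iterations!r}")
        if not 0.0 <= self.degradation_rate <= 1.0:
            raise ValueError(
                f"degradation rate must lie in [0, 1], got {self.degradation_rate!r}"
            )


@dataclass(frozen=True)
class Trajectory:
    """Activity levels over time: one row per node, one column per state.

    ``values[:, 0]`` is the initial state; ``values[:, t]`` the state after
    the t-th synchronous update.
    """

    nodes: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.nodes):
            raise ValueError("trajectory row count must equal node count")

    @property
    def iterations(self) -> int:
        return self.values.shape[1] - 1

    def for_node(self, node: str) -> np.ndarray:
        try:
            i = self.nodes.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None
        return self.values[i]

    def final_state(self) -> np.ndarray:
        return self.values[:, -1]

    def to_frame(self, long: bool = False) -> pd.DataFrame:
        """Wide frame (rows = nodes, columns = iteration indices) or long
        frame with columns (node, iteration, activity)."""
        wide = pd.DataFrame(
            self.values,
            index=pd.Index(self.nodes, name="node"),
            columns=pd.RangeIndex(self.values.shape[1], name="iteration"),
        )
        if not long:
            return wide
        return (
            wide.stack().rename("activity").reset_index()
        )

    def to_csv(self, path: str | Path, long: bool = False) -> None:
        self.to_frame(long=long).to_csv(path, index=not long)


def update_node(
    x_prev: float,
    d: float,
    activating_signals: Iterable[float] = (),
    inhibiting_signals: Iterable[float] = (),
    clamp: bool = True,
) -> float:
    """Apply the update rule to a single node.

    ``activating_signals`` / ``inhibiting_signals`` are the incoming signals
    ``A_i`` / ``B_j`` (parent activity x edge weight, virtual edges included),
    each in [0, 1].  Empty products equal 1, so with no activators the
    activation term vanishes and with no inhibitors the blocking term does.
    """
    if not 0.0 <= x_prev <= 1.0:
        raise ValueError(f"previous activity must lie in [0, 1], got {x_prev!r}")
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"degradation rate must lie in [0, 1], got {d!r}")
    pa = 1.0
    for a in activating_signals:
        if not 0.0 <= a <= 1.0:
            raise ValueError(f"activating signal outside [0, 1]: {a!r}")
        pa *= 1.0 - a
    pb = 1.0
    for b in inhibiting_signals:
        if not 0.0 <= b <= 1.0:
            raise ValueError(f"inhibiting signal outside [0, 1]: {b!r}")
        pb *= 1.0 - b
    x = (1.0 - d) * x_prev + (1.0 - pa) * pb * (1.0 - x_prev) - pa * (1.0 - pb) * x_prev
    if clamp:
        x = min(1.0, max(0.0, x))
    return x


class CompiledNetwork:
    """Flat array form of a network for fast repeated simulation.

    Incoming edges are grouped by target and sign into parent-index and
    weight arrays so that one synchronous step is a handful of vectorised
    numpy operations.  ``set_edge_weights`` swaps in new weights without
    re-deriving the topology — the robustness analysis resamples weights
    thousands of times on a fixed topology.
    """

    def __init__(self, net: SignalingNetwork) -> None:
        self.net = net
        self.nodes = net.nodes
        n = len(net.nodes)
        index = {ident: i for i, ident in enumerate(net.nodes)}
        self._input_index = {index[ident] for ident in net.input_nodes}
        self._node_index = index

        act: list[list[int]] = [[] for _ in range(n)]
        inh: list[list[int]] = [[] for _ in range(n)]
        # remember, per edge, where its weight lives in the flat arrays
        self._edge_slot: list[tuple[bool, int]] = []
        act_src: list[int] = []
        inh_src: list[int] = []
        for e in net.edges:
            s, t = index[e.source], index[e.target]
            if e.sign == ACTIVATING:
                act[t].append(len(act_src))
                act_src.append(s)
                self._edge_slot.append((True, len(act_src) - 1))
            else:
                inh[t].append(len(inh_src))
                inh_src.append(s)
                self._edge_slot.append((False, len(inh_src) - 1))

        def pack(groups: list[list[int]], src: list[int]):
            order = [slot for g in groups for slot in g]
            counts = np.array([len(g) for g in groups], dtype=np.intp)
            perm = np.array(order, dtype=np.intp)
            srcs = np.array([src[slot] for slot in order], dtype=np.intp)
            offsets = np.concatenate(([0], np.cumsum(counts)))
            nonempty = np.flatnonzero(counts)
            starts = offsets[nonempty]
            return perm, srcs, nonempty, starts

        self._act_perm, self._act_src, self._act_nodes, self._act_starts = pack(act, act_src)
        self._inh_perm, self._inh_src, self._inh_nodes, self._inh_starts = pack(inh, inh_src)
        self._act_w = np.empty(len(act_src))
        self._inh_w = np.empty(len(inh_src))
        self.set_edge_weights([e.weight for e in net.edges])

    def set_edge_weights(self, weights: Sequence[float]) -> None:
        """Replace all edge weights, in ``net.edges`` order."""
        if len(weights) != len(self._edge_slot):
            raise ValueError(
                f"expected {len(self._edge_slot)} weights, got {len(weights)}"
            )
        for (is_act, slot), w in zip(self._edge_slot, weights):
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"edge weight outside [0, 1]: {w!r}")
            if is_act:
                self._act_w[slot] = w
            else:
                self._inh_w[slot] = w
        # reorder into the packed (grouped-by-target) layout
        self._act_packed = self._act_w[self._act_perm]
        self._inh_packed = self._inh_w[self._inh_perm]

    def _products(self, state: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-node ``prod(1 - A_i)`` and ``prod(1 - B_j)``."""
        n = len(self.nodes)
        pa = np.ones(n)
        if self._act_src.size:
            terms = 1.0 - state[self._act_src] * self._act_packed
            pa[self._act_nodes] = np.multiply.reduceat(terms, self._act_starts)
        pb = np.ones(n)
        if self._inh_src.size:
            terms = 1.0 - state[self._inh_src] * self._inh_packed
            pb[self._inh_nodes] = np.multiply.reduceat(terms, self._inh_starts)
        return pa, pb

    def step(
        self,
        state: np.ndarray,
        schedule: Schedule | None,
        iteration: int,
        d: float,
        clamp: bool = True,
    ) -> np.ndarray:
        """One synchronous update of the whole state vector."""
        pa, pb = self._products(state)
        if schedule is not None:
            for target, sign, weight in schedule.virtual_edges(iteration):
                try:
                    i = self._node_index[target]
                except KeyError:
                    raise ValueError(f"schedule targets unknown node {target!r}") from None
                # virtual node activity is pinned to 1: signal = weight
                if sign == ACTIVATING:
                    pa[i] *= 1.0 - weight
                else:
                    pb[i] *= 1.0 - weight
        new = (1.0 - d) * state + (1.0 - pa) * pb * (1.0 - state) - pa * (1.0 - pb) * state
        if clamp:
            np.clip(new, 0.0, 1.0, out=new)
        return new

    def initial_state(self, config: SimulationConfig) -> np.ndarray:
        n = len(self.nodes)
        if config.initial_state is None:
            rng = np.random.default_rng(config.seed)
            return rng.uniform(0.0, 1.0, size=n)
        if isinstance(config.initial_state, Mapping):
            missing = set(config.initial_state) - set(self.nodes)
            if missing:
                raise ValueError(f"initial state names unknown nodes: {sorted(missing)}")
            rng = np.random.default_rng(config.seed)
            state = rng.uniform(0.0, 1.0, size=n)
            for ident, v in config.initial_state.items():
                state[self._node_index[ident]] = v
        else:
            state = np.asarray(config.initial_state, dtype=float)
            if state.shape != (n,):
                raise ValueError(
                    f"initial state has shape {state.shape}, expected ({n},)"
                )
            state = state.copy()
        if np.any((state < 0.0) | (state > 1.0)):
            raise ValueError("initial activities must lie in [0, 1]")
        return state

    def run(self, schedule: Schedule | None, config: SimulationConfig) -> Trajectory:
        if schedule is not None:
            bad = schedule.targets - set(self.net.input_nodes)
            if bad:
                raise ValueError(
                    f"schedule targets non-input nodes: {sorted(bad)}; "
                    "declare them as input nodes first"
                )
        n, n_it = len(self.nodes), config.iterations
        values = np.empty((n, n_it + 1))
        values[:, 0] = self.initial_state(config)
        d = config.degradation_rate
        for t in range(1, n_it + 1):
            values[:, t] = self.step(values[:, t - 1], schedule, t, d, config.clamp)
        return Trajectory(self.nodes, values)


def step(
    net: SignalingNetwork,
    state: Sequence[float],
    schedule: Schedule | None,
    iteration: int,
    config: SimulationConfig,
) -> np.ndarray:
    """One synchronous update: every node recomputed from the same previous
    state vector, with active virtual edges included among the parents."""
    state = np.asarray(state, dtype=float)
    compiled = CompiledNetwork(net)
    if state.shape != (len(net.nodes),):
        raise ValueError(
            f"state has shape {state.shape}, expected ({len(net.nodes)},)"
        )
    return compiled.step(state, schedule, iteration, config.degradation_rate, config.clamp)


def run(
    net: SignalingNetwork,
    schedule: Schedule | None,
    config: SimulationConfig,
) -> Trajectory:
    """Simulate ``config.iterations`` synchronous updates of ``net`` under
    ``schedule``; deterministic given the config seed."""
    return CompiledNetwork(net).run(schedule, config)


def detect_stable_state(
    traj: Trajectory, tol: float = 1e-4, window: int = 5
) -> dict[str, float] | None:
    """The final state if the trajectory has settled, else ``None``.

    The trajectory is considered stable when the largest per-node change over
    the last ``window`` consecutive transitions is below ``tol``.  Sustained
    oscillations (e.g. a two-cycle) therefore report ``None``.
    """
    if not tol > 0:
        raise ValueError(f"tol must be positive, got {tol!r}")
    if not (isinstance(window, int) and window >= 1):
        raise ValueError(f"window must be an integer >= 1, got {window!r}")
    n_cols = traj.values.shape[1]
    if window >= n_cols:
        raise ValueError(
            f"window ({window}) must be smaller than the number of stored "
            f"states ({n_cols})"
        )
    diffs = np.abs(np.diff(traj.values[:, -(window + 1):], axis=1))
    if diffs.max(initial=0.0) < tol:
        final = traj.values[:, -1]
        return {ident: float(v) for ident, v in zip(traj.nodes, final)}
    return None
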