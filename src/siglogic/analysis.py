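"""Evaluation procedures for simulated signaling dynamics.

Four procedures, mirroring how logical-model simulations are judged against
time-course phosphoproteomics measurements:

* :func:`downsample` — extract T equally spaced iterations from a trajectory
  so it can be compared with T measured time points (e.g. 32 iterations
  downsampled to the 4th, 8th, ..., 32nd for an 8-point experiment).
* :func:`spearman_fit` — Spearman rank correlation as the goodness-of-fit
  between a simulated and a measured time course (trends matter, absolute
  scale does not).
* :func:`initial_value_sweep` — how the choice of a node's initial activity
  affects its stable level and the time needed to reach it.
* :func:`robustness_analysis` — edge-weight robustness: does the per-node
  activity trend survive randomising all edge weights?  A background trend
  (mean over many weight-randomised runs) is compared, per node, with the
  mean trends of further randomised groups via Spearman correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network import SignalingNetwork
from .perturbation import PerturbationEvent, Schedule
from .simulate import CompiledNetwork, SimulationConfig, Trajectory

__all__ = [
    "MeasuredTimeCourse",
    "RobustnessResult",
    "SweepResult",
    "FitReport",
    "downsample",
    "spearman_fit",
    "initial_value_sweep",
    "robustness_analysis",
    "condition_fit_report",
    "uniform_weight_sampler",
    "constant_weight_sampler",
]

logger = logging.getLogger(__name__)

WeightSampler = Callable[[np.random.Generator, int], np.ndarray]


def uniform_weight_sampler(rng: np.random.Generator, n_edges: int) -> np.ndarray:
    """i.i.d. uniform [0, 1) weight per edge — the default randomisation."""
    return rng.uniform(0.0, 1.0, size=n_edges)


def constant_weight_sampler(value: float) -> WeightSampler:
    """A point-mass sampler: every edge gets ``value`` (degenerate case used
    to check that zero weight variance yields correlation 1)."""
    def sample(rng: np.random.Generator, n_edges: int) -> np.ndarray:
        return np.full(n_edges, value)
    return sample


@dataclass(frozen=True)
class MeasuredTimeCourse:
    """A protein x time-point table of measured activity levels.

    Values are nonnegative reals (measurements normalised onto the same
    scale as simulated activities).  Missing cells are not allowed: impute
    or drop rows before constructing.
    """

    proteins: tuple[str, ...]
    time_points: tuple[int, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.proteins), len(self.time_points)):
            raise ValueError(
                f"values shape {v.shape} does not match "
                f"{len(self.proteins)} proteins x {len(self.time_points)} time points"
            )
        if len(self.time_points) < 2:
            raise ValueError("a time course needs at least 2 time points")
        if np.any(~np.isfinite(v)):
            raise ValueError("missing/non-finite cells: impute or drop rows first")
        if np.any(v < 0):
            raise ValueError("measured values must be nonnegative")

    def row(self, protein: str) -> np.ndarray:
        try:
            i = self.proteins.index(protein)
        except ValueError:
            raise KeyError(f"unknown protein {protein!r}") from None
        return self.values[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.proteins, name="protein"),
            columns=self.time_points,
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeasuredTimeCourse":
        """First column protein identifiers, remaining columns numeric."""
        frame = pd.read_csv(path, index_col=0)
        frame = frame.dropna(axis=0, how="any")
        return cls(
            proteins=tuple(str(p) for p in frame.index),
            time_points=tuple(int(float(c)) for c in frame.columns),
            values=frame.to_numpy(dtype=float),
        )


def downsample(traj: Trajectory, n_points: int) -> pd.DataFrame:
    """Extract ``n_points`` equally spaced iterations from a trajectory.

    For N iterations and T points the columns taken are iterations
    N/T, 2N/T, ..., N (1-based; the initial state is never included), e.g.
    32 iterations at T = 8 yields the 4th, 8th, ..., 32nd states.  N must be
    divisible by T — no silent interpolation.
    """
    n_iter = traj.iterations
    if not (isinstance(n_points, int) and n_points >= 1):
        raise ValueError(f"n_points must be a positive integer, got {n_points!r}")
    if n_iter % n_points != 0:
        raise ValueError(
            f"iteration count ({n_iter}) must be divisible by the number of "
            f"time points ({n_points}); choose a compatible iteration count"
        )
    stride = n_iter // n_points
    cols = np.arange(1, n_points + 1) * stride
    return pd.DataFrame(
        traj.values[:, cols],
        index=pd.Index(traj.nodes, name="node"),
        columns=cols,
    )


def spearman_fit(simulated: Sequence[float], measured: Sequence[float]) -> float:
    """Spearman rank correlation between a simulated and a measured time
    course (average ranks for ties).

    Returns NaN — a flagged not-a-value, never silently 0 — when either
    vector is constant, where rank correlation is undefined.
    """
    sim = np.asarray(simulated, dtype=float)
    mea = np.asarray(measured, dtype=float)
    if sim.shape != mea.shape or sim.ndim != 1:
        raise ValueError(
            f"expected two equal-length vectors, got shapes {sim.shape} and {mea.shape}"
        )
    if sim.size < 3:
        raise ValueError(f"need at least 3 time points, got {sim.size}")
    if np.all(sim == sim[0]) or np.all(mea == mea[0]):
        return float("nan")
    rho = stats.spearmanr(sim, mea).statistic
    return float(rho)


@dataclass(frozen=True)
class SweepResult:
    """Outcome of one run in an initial-value sweep."""

    initial_value: float
    trajectory: Trajectory
    stable_level: float | None
    time_to_stability: int | None


def initial_value_sweep(
    net: SignalingNetwork,
    schedule: Schedule | None,
    config: SimulationConfig,
    node: str,
    initial_values: Sequence[float],
    stability_tol: float = 0.01,
) -> list[SweepResult]:
    """Rerun the simulation with several initial activities for one node.

    All runs share the seeded random initial activities of the *other*
    nodes; only ``node``'s initial value is swept.  For each run the stable
    level of ``node`` (``None`` if the trajectory has not settled) and the
    first iteration from which ``node`` stays within ``stability_tol`` of
    that level are reported.  Used to check that initial values change the
    time to the stable state but not the stable state itself.
    """
    if node not in net:
        raise KeyError(f"unknown node {node!r}")
    for v in initial_values:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"initial value outside [0, 1]: {v!r}")
    compiled = CompiledNetwork(net)
    base = compiled.initial_state(
        SimulationConfig(
            iterations=config.iterations,
            degradation_rate=config.degradation_rate,
            seed=config.seed,
        )
    )
    idx = net.index_of(node)
    window = min(5, config.iterations)
    results = []
    for v in initial_values:
        init = base.copy()
        init[idx] = v
        cfg = SimulationConfig(
            iterations=config.iterations,
            degradation_rate=config.degradation_rate,
            initial_state=init,
            clamp=config.clamp,
        )
        traj = compiled.run(schedule, cfg)
        series = traj.for_node(node)
        # the swept node counts as settled when its own trajectory stops
        # moving, regardless of slower nodes elsewhere in the network
        tail = np.abs(np.diff(series[-(window + 1):]))
        if tail.max(initial=0.0) >= stability_tol / 10.0:
            results.append(SweepResult(float(v), traj, None, None))
            continue
        level = float(series[-1])
        within = np.abs(series - level) < stability_tol
        # first index from which the node stays within tolerance for good
        t_stab = int(np.flatnonzero(~within).max() + 1) if (~within).any() else 0
        results.append(SweepResult(float(v), traj, level, t_stab))
    return results


@dataclass(frozen=True)
class RobustnessResult:
    """Per-node distributions of group-trend vs background-trend
    correlations from the edge-weight robustness analysis.

    ``correlations[node]`` holds one Spearman coefficient per group; NaN
    marks groups where the correlation was undefined (constant trend).
    Nodes without incoming edges (receptors/stimuli) are excluded — their
    trends do not depend on edge weights.
    """

    nodes: tuple[str, ...]
    correlations: dict[str, np.ndarray] = field(compare=False)
    background_trend: pd.DataFrame = field(compare=False)

    def median(self, node: str) -> float:
        vals = self.correlations[node]
        defined = vals[~np.isnan(vals)]
        return float(np.median(defined)) if defined.size else float("nan")

    def medians(self) -> pd.Series:
        return pd.Series({n: self.median(n) for n in self.nodes}, name="median")

    def ranked(self) -> pd.Series:
        """Nodes ranked by median correlation, most robust first."""
        return self.medians().sort_values(ascending=False)

    def to_frame(self) -> pd.DataFrame:
        """One row per node, one column per group, plus a median column."""
        frame = pd.DataFrame.from_dict(self.correlations, orient="index")
        frame.index.name = "node"
        frame.columns = [f"group_{g}" for g in range(frame.shape[1])]
        frame["median"] = self.medians()
        return frame.loc[list(self.nodes)]


def _mean_trend(
    compiled: CompiledNetwork,
    schedule: Schedule | None,
    base: SimulationConfig,
    n_runs: int,
    sampler: WeightSampler,
    weight_seeds: np.ndarray,
    init_seeds: np.ndarray,
) -> np.ndarray:
    """Mean post-initial activity per node over ``n_runs`` simulations, each
    with freshly sampled edge weights and a random initial state.

    Initial-state seeds are indexed by run position so that the k-th run of
    every group (and of the background) shares its initial state; only the
    weight randomisation distinguishes groups.  A degenerate (point-mass)
    weight sampler then makes equal-sized group and background trends
    literally identical.
    """
    total = np.zeros((len(compiled.nodes), base.iterations))
    n_edges = len(compiled.net.edges)
    for k in range(n_runs):
        w_rng = np.random.default_rng(weight_seeds[k])
        weights = np.asarray(sampler(w_rng, n_edges), dtype=float)
        compiled.set_edge_weights(weights)
        init_rng = np.random.default_rng(init_seeds[k])
        cfg = SimulationConfig(
            iterations=base.iterations,
            degradation_rate=base.degradation_rate,
            initial_state=init_rng.uniform(0.0, 1.0, size=len(compiled.nodes)),
            clamp=base.clamp,
        )
        traj = compiled.run(schedule, cfg)
        total += traj.values[:, 1:]
    return total / n_runs


def robustness_analysis(
    net: SignalingNetwork,
    schedule: Schedule | None,
    config: SimulationConfig,
    n_background: int = 100,
    n_groups: int = 50,
    group_size: int = 100,
    weight_sampler: WeightSampler | None = None,
) -> RobustnessResult:
    """Edge-weight robustness of per-node activity trends.

    First ``n_background`` simulations, each with freshly sampled edge
    weights (topology and signs fixed) and random initial activities, define
    the *background trend*: the per-node mean activity at each iteration.
    Then each of ``n_groups`` groups of ``group_size`` equally randomised
    simulations yields a group mean trend, and per node the Spearman
    correlation between group trend and background trend is recorded.  Tight
    correlation distributions near 1 indicate trends that are robust to the
    choice of edge weights.

    Nodes with no incoming edges are excluded.  Groups whose trend is
    constant for a node get NaN for that node, never an imputed value.
    ``config.seed`` drives all randomisation.  Initial states are paired by
    run index across the background and every group, so only the weight
    randomisation distinguishes groups; with a point-mass sampler and
    ``group_size == n_background`` every group trend equals the background
    trend exactly and all defined correlations are 1.
    """
    for name, v in (("n_background", n_background), ("n_groups", n_groups),
                    ("group_size", group_size)):
        if not (isinstance(v, int) and v >= 1):
            raise ValueError(f"{name} must be a positive integer, got {v!r}")
    sampler = weight_sampler if weight_sampler is not None else uniform_weight_sampler
    compiled = CompiledNetwork(net)
    kept = [ident for ident in net.nodes if net.in_degree(ident) > 0]
    if not kept:
        raise ValueError("no node has incoming edges; nothing to analyse")

    init_ss, weight_ss = np.random.SeedSequence(config.seed).spawn(2)
    max_runs = max(n_background, group_size)
    init_seeds = init_ss.generate_state(max_runs, dtype=np.uint32)
    weight_seeds = weight_ss.generate_state((1 + n_groups) * max_runs,
                                            dtype=np.uint32).reshape(1 + n_groups, max_runs)
    bg = _mean_trend(compiled, schedule, config, n_background, sampler,
                     weight_seeds[0], init_seeds)
    bg_frame = pd.DataFrame(
        bg, index=pd.Index(net.nodes, name="node"),
        columns=np.arange(1, config.iterations + 1),
    )

    corrs = {ident: np.empty(n_groups) for ident in kept}
    for g in range(n_groups):
        trend = _mean_trend(compiled, schedule, config, group_size, sampler,
                            weight_seeds[g + 1], init_seeds)
        for ident in kept:
            i = net.index_of(ident)
            corrs[ident][g] = spearman_fit(trend[i], bg[i])
    return RobustnessResult(tuple(kept), corrs, bg_frame)


@dataclass(frozen=True)
class FitReport:
    """Per-protein, per-condition goodness of fit, plus skipped proteins."""

    table: pd.DataFrame
    skipped: dict[str, tuple[str, ...]]


def _schedule_for_design(design: Mapping[str, float | str]) -> Schedule:
    events = []
    for node, level in design.items():
        if isinstance(level, str):
            if level.lower() not in ("random", "random value"):
                raise ValueError(
                    f"design level for {node!r} must be a number in [-1, 1] "
                    f"or 'random', got {level!r}"
                )
            # unconstrained input: no virtual edge; the node starts at a
            # seeded random activity and evolves by degradation
            continue
        events.append(PerturbationEvent(target=node, level=float(level), start=1))
    return Schedule(events)


def condition_fit_report(
    net: SignalingNetwork,
    designs: Mapping[str, Mapping[str, float | str]],
    measured: Mapping[str, MeasuredTimeCourse],
    config: SimulationConfig,
) -> FitReport:
    """Goodness of fit of simulated dynamics to measurements, per condition.

    ``designs`` maps a condition name to its input assignment: each input
    node gets either a level in [-1, 1] (applied from iteration 1 as a
    virtual-edge perturbation) or ``"random"`` (no virtual edge; seeded
    random initial activity, free evolution).  For every condition the
    network is simulated, downsampled to the measured number of time points
    and correlated per shared protein with that condition's measurements.

    Proteins measured but absent from the network are listed as skipped,
    never fatal.  Returns a proteins x conditions table of Spearman
    coefficients.
    """
    unknown = set(designs) - set(measured)
    if unknown:
        raise ValueError(f"no measurements supplied for conditions: {sorted(unknown)}")
    columns: dict[str, pd.Series] = {}
    skipped: dict[str, tuple[str, ...]] = {}
    for cond, design in designs.items():
        mtc = measured[cond]
        schedule = _schedule_for_design(design)
        traj = CompiledNetwork(net).run(schedule, config)
        sim = downsample(traj, len(mtc.time_points))
        shared = [p for p in mtc.proteins if p in net]
        skip = tuple(p for p in mtc.proteins if p not in net)
        if skip:
            skipped[cond] = skip
            logger.warning(
                "condition %r: %d measured proteins absent from the network, "
                "skipped: %s", cond, len(skip), ", ".join(skip)
            )
        if not shared:
            logger.warning("condition %r: no measured protein overlaps the network", cond)
        columns[cond] = pd.Series(
            {p: spearman_fit(sim.loc[p].to_numpy(), mtc.row(p)) for p in shared},
            dtype=float,
        )
    table = pd.DataFrame(columns)
    table.index.name = "protein"
    return FitReport(table=table, skipped=skipped)
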