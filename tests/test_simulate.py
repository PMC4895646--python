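"""Simulation engine: the update rule, synchronous stepping, trajectories,
stable-state detection, and the Boolean special case."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import siglogic as sl


def naive_update(x, d, acts, inhs):
    """Brute-force transcription of the update rule, written independently
    of the implementation: explicit loops, no clamping, no vectorisation."""
    prod_a = 1.0
    for a in acts:
        prod_a = prod_a * (1.0 - a)
    prod_b = 1.0
    for b in inhs:
        prod_b = prod_b * (1.0 - b)
    activation = (1.0 - prod_a) * prod_b * (1.0 - x)
    blocking = prod_a * (1.0 - prod_b) * x
    return (1.0 - d) * x + activation - blocking


class TestUpdateNode:
    def test_no_parents_no_degradation_is_identity(self):
        assert sl.update_node(0.5, 0.0) == 0.5

    def test_hand_computed_example(self):
        # 0.8*0.5 + 0.6*0.7*0.5 - 0.4*0.3*0.5 = 0.55
        got = sl.update_node(0.5, 0.2, [0.6], [0.3])
        assert got == pytest.approx(0.55, abs=1e-12)

    def test_clamping_floors_negative_raw_value(self):
        # raw value: -1*0.5 + 0 - 1*1*0.5 = wait, d=1: 0*0.5 - 1*0.5 = -0.5
        assert naive_update(0.5, 1.0, [], [1.0]) == pytest.approx(-0.5)
        assert sl.update_node(0.5, 1.0, [], [1.0]) == 0.0
        assert sl.update_node(0.5, 1.0, [], [1.0], clamp=False) == pytest.approx(-0.5)

    def test_agrees_with_bruteforce_oracle_on_random_tuples(self):
        rng = np.random.default_rng(2024)
        for _ in range(1500):
            x = rng.uniform()
            d = rng.uniform()
            acts = list(rng.uniform(size=rng.integers(0, 5)))
            inhs = list(rng.uniform(size=rng.integers(0, 5)))
            expected = naive_update(x, d, acts, inhs)
            got = sl.update_node(x, d, acts, inhs, clamp=False)
            assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [
        dict(x_prev=1.5, d=0.2),
        dict(x_prev=0.5, d=-0.1),
        dict(x_prev=0.5, d=0.2, activating_signals=[1.2]),
        dict(x_prev=0.5, d=0.2, inhibiting_signals=[-0.1]),
    ])
    def test_out_of_range_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            sl.update_node(**bad)


class TestStep:
    def test_unit_chain_propagates_in_one_step(self):
        net = sl.SignalingNetwork(
            ["A", "B"], [sl.Edge("A", "B", sl.ACTIVATING, 1.0)], ["A"])
        cfg = sl.SimulationConfig(iterations=1, degradation_rate=0.0)
        out = sl.step(net, [1.0, 0.0], None, 1, cfg)
        np.testing.assert_allclose(out, [1.0, 1.0])

    def test_isolated_node_pure_degradation(self):
        net = sl.SignalingNetwork(["A"], ())
        cfg = sl.SimulationConfig(iterations=1, degradation_rate=0.2)
        out = sl.step(net, [0.5], None, 1, cfg)
        np.testing.assert_allclose(out, [0.4])

    def test_synchronous_update_matches_per_node_oracle(self, toy_net):
        """Every node updates from the SAME previous state: the vectorised
        step must equal update_node applied node-by-node to the old state."""
        rng = np.random.default_rng(5)
        state = rng.uniform(size=toy_net.n_nodes)
        cfg = sl.SimulationConfig(iterations=1, degradation_rate=0.2)
        out = sl.step(toy_net, state, None, 1, cfg)
        for i, ident in enumerate(toy_net.nodes):
            act, inh = toy_net.parents_of(ident)
            acts = [state[toy_net.index_of(p)] * w for p, w in act]
            inhs = [state[toy_net.index_of(p)] * w for p, w in inh]
            assert out[i] == pytest.approx(
                sl.update_node(state[i], 0.2, acts, inhs), abs=1e-12)

    def test_node_order_permutation_permutes_output(self, toy_net):
        perm_nodes = tuple(reversed(toy_net.nodes))
        perm_net = sl.SignalingNetwork(perm_nodes, toy_net.edges, toy_net.input_nodes)
        rng = np.random.default_rng(6)
        state = rng.uniform(size=toy_net.n_nodes)
        cfg = sl.SimulationConfig(iterations=1, degradation_rate=0.3)
        out = sl.step(toy_net, state, None, 1, cfg)
        out_perm = sl.step(perm_net, state[::-1], None, 1, cfg)
        np.testing.assert_array_equal(out, out_perm[::-1])

    def test_dimension_mismatch_rejected(self, toy_net):
        cfg = sl.SimulationConfig(iterations=1)
        with pytest.raises(ValueError, match="shape"):
            sl.step(toy_net, [0.5, 0.5], None, 1, cfg)

    def test_virtual_edge_included_among_parents(self, one_node_net):
        sched = sl.Schedule([sl.PerturbationEvent("R", -1.0, start=1)])
        cfg = sl.SimulationConfig(iterations=1, degradation_rate=0.0)
        # full inhibition: blocking term removes the whole active fraction
        out = sl.step(one_node_net, [0.9], sched, 1, cfg)
        np.testing.assert_allclose(out, [0.0])


class TestRun:
    def test_stimulated_receptor_converges_to_input_level(self, one_node_net):
        """Stimulus level 0.8 with d = 0.2 plateaus at activity 0.8, the
        fixed point A/(A+d) = 0.8/(0.8+0.2)."""
        sched = sl.Schedule([sl.PerturbationEvent("R", 0.8, start=20)])
        cfg = sl.SimulationConfig(iterations=100, degradation_rate=0.2, seed=1)
        traj = sl.run(one_node_net, sched, cfg)
        assert traj.values.shape == (1, 101)
        assert abs(traj.values[0, -1] - 0.8) < 0.01
        # plateau reached shortly after the stimulus starts
        assert np.all(np.abs(traj.values[0, 30:] - 0.8) < 0.01)

    def test_fixed_point_closed_form(self):
        """Constant activating signal A with degradation d converges to
        A/(A+d) for any A + d > 0."""
        for level, d in [(0.8, 0.2), (0.5, 0.2), (0.3, 0.05), (1.0, 1.0)]:
            net = sl.SignalingNetwork(["R"], (), ["R"])
            sched = sl.Schedule([sl.PerturbationEvent("R", level, start=1)])
            cfg = sl.SimulationConfig(iterations=300, degradation_rate=d,
                                      initial_state=[0.5])
            traj = sl.run(net, sched, cfg)
            assert traj.values[0, -1] == pytest.approx(level / (level + d), abs=1e-9)

    def test_fixed_point_independent_of_seed(self, one_node_net):
        sched = sl.Schedule([sl.PerturbationEvent("R", 0.8, start=20)])
        trajs = [
            sl.run(one_node_net, sched,
                   sl.SimulationConfig(iterations=100, degradation_rate=0.2, seed=s))
            for s in (1, 2)
        ]
        assert trajs[0].values[0, 0] != trajs[1].values[0, 0]
        np.testing.assert_allclose(trajs[0].values[0, 40:], trajs[1].values[0, 40:],
                                   atol=1e-6)

    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError, match="iterations"):
            sl.SimulationConfig(iterations=0)

    def test_schedule_on_non_input_node_rejected(self, toy_net):
        sched = sl.Schedule([sl.PerturbationEvent("ERK", 0.5)])
        cfg = sl.SimulationConfig(iterations=10, seed=0)
        with pytest.raises(ValueError, match="non-input"):
            sl.run(toy_net, sched, cfg)

    def test_determinism_bit_identical(self, toy_net):
        sched = sl.Schedule([sl.PerturbationEvent("EGFR", 0.5)])
        cfg = sl.SimulationConfig(iterations=50, degradation_rate=0.2, seed=123)
        a = sl.run(toy_net, sched, cfg)
        b = sl.run(toy_net, sched, cfg)
        assert np.array_equal(a.values, b.values)

    def test_fixed_initial_vector_and_mapping(self, chain_net):
        cfg = sl.SimulationConfig(iterations=5, degradation_rate=0.0,
                                  initial_state=[1.0, 0.0, 0.0])
        traj = sl.run(chain_net, None, cfg)
        np.testing.assert_array_equal(traj.values[:, 0], [1.0, 0.0, 0.0])
        cfg2 = sl.SimulationConfig(iterations=5, seed=3,
                                   initial_state={"A": 1.0})
        traj2 = sl.run(chain_net, None, cfg2)
        assert traj2.values[0, 0] == 1.0


binary_networks = st.builds(
    lambda n_nodes, density_seed: sl.generate_network(
        sl.NetworkSpec(
            n_nodes=n_nodes,
            n_edges=(n_nodes * (n_nodes - 1)) * (density_seed % 3 + 1) // 4,
            activating_fraction=0.6,
            weight_sampler=lambda rng, k: np.ones(k),
            n_inputs=0,
            seed=density_seed,
        )
    ),
    n_nodes=st.integers(2, 4),
    density_seed=st.integers(0, 2**31 - 1),
)


class TestBooleanLimit:
    """With d = 0, unit weights and binary states the model reduces to the
    induced Boolean rule: any active activator and no active inhibitor turns
    the node on; no active activator and an active inhibitor turns it off;
    otherwise the node holds its state."""

    @staticmethod
    def boolean_next(net, state):
        out = {}
        for ident in net.nodes:
            act, inh = net.parents_of(ident)
            any_act = any(state[p] for p, _ in act)
            any_inh = any(state[p] for p, _ in inh)
            if any_act and not any_inh:
                out[ident] = 1
            elif not any_act and any_inh:
                out[ident] = 0
            else:
                out[ident] = state[ident]
        return out

    @settings(max_examples=30, deadline=None)
    @given(net=binary_networks)
    def test_exhaustive_state_enumeration_matches_boolean_rule(self, net):
        n = net.n_nodes
        cfg = sl.SimulationConfig(iterations=1, degradation_rate=0.0)
        for bits in range(2 ** n):
            state = [(bits >> i) & 1 for i in range(n)]
            expected = self.boolean_next(net, dict(zip(net.nodes, map(float, state))))
            got = sl.step(net, [float(b) for b in state], None, 1, cfg)
            assert [int(v) for v in got] == [expected[ident] for ident in net.nodes]


@settings(max_examples=25, deadline=None)
@given(
    seed=st.integers(0, 2**31 - 1),
    d=st.floats(0.0, 1.0),
    level=st.floats(-1.0, 1.0),
)
def test_trajectories_stay_in_unit_interval(seed, d, level):
    """With clamping on, every activity stays in [0, 1] for arbitrary valid
    networks, degradation rates and schedules."""
    net = sl.generate_network(sl.NetworkSpec(n_nodes=6, n_edges=14, n_inputs=2,
                                             seed=seed))
    sched = sl.Schedule([sl.PerturbationEvent(net.input_nodes[0], level, start=3)])
    cfg = sl.SimulationConfig(iterations=40, degradation_rate=d, seed=seed)
    traj = sl.run(net, sched, cfg)
    assert traj.values.min() >= 0.0
    assert traj.values.max() <= 1.0


class TestDetectStableState:
    def test_constant_trajectory_returns_constant_vector(self):
        traj = sl.Trajectory(("A",), np.full((1, 11), 0.3))
        assert sl.detect_stable_state(traj) == {"A": 0.3}

    def test_pure_decay_reaches_zero(self):
        """A parentless node with d = 0.2 decays as 0.8^t X0 -> 0."""
        net = sl.SignalingNetwork(["A"], ())
        cfg = sl.SimulationConfig(iterations=100, degradation_rate=0.2,
                                  initial_state=[1.0])
        traj = sl.run(net, None, cfg)
        expected = 0.8 ** np.arange(101)
        np.testing.assert_allclose(traj.values[0], expected, atol=1e-15)
        stable = sl.detect_stable_state(traj, tol=1e-4)
        assert stable == {"A": pytest.approx(0.0, abs=1e-8)}

    def test_two_cycle_not_stable(self):
        vals = np.tile([0.0, 1.0], 10)[None, :]
        traj = sl.Trajectory(("A",), vals)
        assert sl.detect_stable_state(traj, tol=1e-4, window=4) is None

    def test_window_must_fit_trajectory(self):
        traj = sl.Trajectory(("A",), np.zeros((1, 5)))
        with pytest.raises(ValueError, match="window"):
            sl.detect_stable_state(traj, window=5)


class TestTrajectoryOutput:
    def test_wide_and_long_frames(self, chain_net, tmp_path):
        cfg = sl.SimulationConfig(iterations=3, seed=0)
        traj = sl.run(chain_net, None, cfg)
        wide = traj.to_frame()
        assert wide.shape == (3, 4)
        assert list(wide.columns) == [0, 1, 2, 3]
        long = traj.to_frame(long=True)
        assert set(long.columns) == {"node", "iteration", "activity"}
        assert len(long) == 12
        traj.to_csv(tmp_path / "t.csv")
        assert (tmp_path / "t.csv").read_text().startswith("node,")
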