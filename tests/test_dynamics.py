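"""Synchronous stepping, trajectory convergence, and successor maps."""

import numpy as np
import pytest

import endmtbn as e
from conftest import TABLE4_ENVIRONMENT, table4_column, table4_cycles


class TestStep:
    def test_reference_columns_step_to_their_successors(self, endmt):
        """Node-wise stepping maps each printed attractor column to the
        next, cyclically within each of the three period-4 attractors
        (complete 29x12 bit-exact check)."""
        for cycle_cols in ([0, 1, 2, 3], [4, 5, 6, 7], [8, 9, 10, 11]):
            for a, b in zip(cycle_cols, cycle_cols[1:] + cycle_cols[:1]):
                nxt = e.step(endmt, table4_column(endmt, a))
                assert np.array_equal(nxt, table4_column(endmt, b)), (a, b)

    def test_toy_step(self, toy3):
        assert np.array_equal(e.step(toy3, [1, 0, 0]), [1, 1, 0])

    def test_step_batch_matches_scalar_step(self, endmt):
        rng = np.random.default_rng(5)
        states = rng.integers(0, 1 << 29, size=200, dtype=np.uint64)
        batch = e.step_batch(endmt, states)
        for s, expected in zip(states[:50], batch[:50]):
            assert e.step_int(endmt, int(s)) == int(expected)

    def test_step_is_deterministic(self, endmt):
        state = table4_column(endmt, 5)
        assert np.array_equal(e.step(endmt, state), e.step(endmt, state))

    def test_sources_never_change(self, endmt):
        rng = np.random.default_rng(9)
        states = rng.integers(0, 1 << 29, size=500, dtype=np.uint64)
        nxt = e.step_batch(endmt, states)
        for name in endmt.source_nodes:
            i = np.uint64(endmt.node_index(name))
            assert np.array_equal((states >> i) & np.uint64(1),
                                  (nxt >> i) & np.uint64(1))


class TestSimulateToAttractor:
    def test_reference_attractor_state_has_zero_transient(self, endmt):
        start = table4_cycles(endmt)[1][0]
        traj = e.simulate_to_attractor(endmt, start, max_steps=100)
        assert traj.transient_length == 0
        assert traj.attractor.period == 4
        assert set(traj.attractor.states) == set(table4_cycles(endmt)[1])

    def test_toy_converges_to_fixed_point(self, toy3):
        traj = e.simulate_to_attractor(toy3, [0, 1, 1])
        assert traj.attractor.period == 1
        assert traj.attractor.states == (0,)
        assert traj.transient_length <= 3

    def test_fixed_point_detected_immediately(self, toy3):
        traj = e.simulate_to_attractor(toy3, [0, 0, 0])
        assert traj.transient_length == 0
        assert traj.attractor.is_fixed_point

    def test_max_steps_guard(self, toy3):
        with pytest.raises(ValueError):
            e.simulate_to_attractor(toy3, [0, 0, 0], max_steps=0)

    def test_trajectory_export(self, toy3, tmp_path):
        traj = e.simulate_to_attractor(toy3, [1, 0, 0])
        frame = traj.to_frame(toy3)
        assert list(frame.columns) == ["A", "B", "C"]
        path = tmp_path / "traj.csv"
        traj.to_csv(toy3, path)
        assert path.exists()


class TestSuccessorMap:
    def test_toy_map_matches_brute_force(self, toy3):
        env = e.Environment.from_assignment(toy3, {"A": 0})
        smap = e.build_successor_map(toy3, env)
        assert smap.size == 4
        # with A=0: B'=0, C'=B; all paths end at (B,C)=(0,0)
        for idx in range(4):
            b, c = idx & 1, (idx >> 1) & 1
            expected = (b << 1)  # B'=0, C'=B
            assert smap.successors[idx] == expected

    def test_endmt_map_agrees_with_scalar_stepping(self, endmt):
        env = e.Environment.from_assignment(endmt, TABLE4_ENVIRONMENT)
        smap = e.build_successor_map(endmt, env)
        assert smap.size == 1 << 22
        free_pos = [endmt.node_index(nd) for nd in smap.free_nodes]
        env_bits = sum(v << endmt.node_index(k)
                       for k, v in TABLE4_ENVIRONMENT.items())
        rng = np.random.default_rng(11)
        for idx in rng.integers(0, 1 << 22, size=25):
            full = env_bits
            for p, pos in enumerate(free_pos):
                full |= ((int(idx) >> p) & 1) << pos
            nxt = e.step_int(endmt, full)
            packed = 0
            for p, pos in enumerate(free_pos):
                packed |= ((nxt >> pos) & 1) << p
            assert int(smap.successors[int(idx)]) == packed

    def test_environment_mismatch_rejected(self, endmt, toy3):
        env = e.Environment.from_assignment(toy3, {"A": 1})
        with pytest.raises(e.NetworkError):
            e.build_successor_map(endmt, env)


class TestEnvironment:
    def test_round_trip_id(self, endmt):
        env = e.Environment.from_assignment(endmt, TABLE4_ENVIRONMENT)
        again = e.Environment.from_id(endmt, env.id)
        assert again.as_dict() == env.as_dict()

    def test_must_cover_all_sources(self, endmt):
        with pytest.raises(e.NetworkError, match="missing"):
            e.Environment.from_assignment(endmt, {"DLL4": 1})

    def test_non_source_rejected(self, endmt):
        full = dict(TABLE4_ENVIRONMENT)
        full["SNAI1"] = 1
        with pytest.raises(e.NetworkError, match="non-source"):
            e.Environment.from_assignment(endmt, full)

    def test_128_environments(self, endmt):
        envs = list(e.dynamics.iter_environments(endmt))
        assert len(envs) == 128
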