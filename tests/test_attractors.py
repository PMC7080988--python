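"""Attractor enumeration: oracle equivalence, canonicalization, and
environment decomposition."""

import numpy as np
import pytest

import endmtbn as e
from conftest import brute_force_attractors, random_network, table4_cycles


class TestOracleEquivalence:
    def test_toy_network(self, toy3):
        atlas = e.enumerate_attractors(toy3)
        keys = {att.states for att in atlas.attractors}
        assert keys == brute_force_attractors(toy3)
        periods = sorted(att.period for att in atlas.attractors)
        assert periods == [1, 4]  # fixed point (0,0,0) and the A=1 cycle

    @pytest.mark.parametrize("n_nodes,seed", [
        (4, 1), (6, 2), (8, 3), (10, 4), (12, 5), (7, 6), (9, 7),
    ])
    def test_random_networks_match_brute_force(self, n_nodes, seed):
        net = random_network(n_nodes, seed)
        atlas = e.enumerate_attractors(net)
        assert {att.states for att in atlas.attractors} == \
            brute_force_attractors(net)


class TestEndMTAtlas:
    def test_reference_environment_has_three_period4_attractors(
            self, endmt, wt_atlas, table4_env):
        atts = e.attractors_in_environment(wt_atlas, table4_env)
        assert len(atts) == 3
        assert all(att.period == 4 for att in atts)
        expected = {
            e.canonicalize(endmt, cycle).canonical_key
            for cycle in table4_cycles(endmt)
        }
        assert {att.canonical_key for att in atts} == expected

    def test_every_environment_contributes(self, wt_atlas):
        assert len(wt_atlas.per_environment) == 128
        assert all(len(v) >= 1 for v in wt_atlas.per_environment.values())

    def test_no_duplicate_canonical_keys(self, wt_atlas):
        keys = [att.canonical_key for att in wt_atlas.attractors]
        assert len(keys) == len(set(keys))

    def test_periods_are_1_2_or_4(self, wt_atlas):
        assert {att.period for att in wt_atlas.attractors} <= {1, 2, 4}

    def test_atlas_sorted_by_environment_then_key(self, wt_atlas):
        order = [(att.environment_id, att.canonical_key)
                 for att in wt_atlas.attractors]
        assert order == sorted(order)

    def test_attractor_states_close_cycles(self, endmt, wt_atlas):
        rng = np.random.default_rng(2)
        for aid in rng.choice(len(wt_atlas.attractors), size=20, replace=False):
            att = wt_atlas.attractors[aid]
            for a, b in zip(att.states, att.states[1:] + att.states[:1]):
                assert e.step_int(endmt, a) == b

    def test_unknown_environment_rejected(self, wt_atlas):
        with pytest.raises(e.NetworkError):
            e.attractors_in_environment(wt_atlas, 999)

    def test_basin_conservation(self, endmt, wt_atlas):
        """Every sampled state resolves to an attractor of its own
        environment (the basins cover the state space)."""
        rng = np.random.default_rng(3)
        states = rng.integers(0, 1 << 29, size=20_000, dtype=np.uint64)
        ids = wt_atlas.resolver.resolve(states)
        for s, aid in zip(states[:200], ids[:200]):
            att = wt_atlas.attractors[aid]
            env_bits = [(int(s) >> endmt.node_index(nd)) & 1
                        for nd in endmt.source_nodes]
            assert att.environment_id == e.pack_state(env_bits)


class TestCanonicalize:
    def test_rotation_invariance(self, endmt):
        for cycle in table4_cycles(endmt):
            keys = set()
            for r in range(len(cycle)):
                rotated = cycle[r:] + cycle[:r]
                att = e.canonicalize(endmt, rotated)
                keys.add((att.canonical_key, att.states))
            assert len(keys) == 1

    def test_fixed_point(self, toy3):
        att = e.canonicalize(toy3, [0])
        assert att.period == 1 and att.canonical_key == 0

    def test_non_cycle_rejected(self, endmt):
        with pytest.raises(e.NetworkError):
            e.canonicalize(endmt, [0, 1])

    def test_printed_cycle_order_is_step_consistent(self, endmt):
        att = e.canonicalize(endmt, table4_cycles(endmt)[1])
        assert att.period == 4


class TestResolver:
    def test_resolve_agrees_with_scalar_simulation(self, endmt, wt_atlas):
        rng = np.random.default_rng(4)
        states = rng.integers(0, 1 << 29, size=60, dtype=np.uint64)
        ids = wt_atlas.resolver.resolve(states)
        for s, aid in zip(states, ids):
            traj = e.simulate_to_attractor(endmt, int(s))
            assert traj.attractor.canonical_key == \
                wt_atlas.attractors[aid].canonical_key

    def test_attractor_states_resolve_to_themselves(self, wt_atlas):
        firsts = np.array([att.states[0] for att in wt_atlas.attractors],
                          dtype=np.uint64)
        ids = wt_atlas.resolver.resolve(firsts)
        assert np.array_equal(ids, np.arange(len(wt_atlas.attractors)))


def test_reduced_census_matches_full_successor_map(endmt, wt_atlas, table4_env):
    """Dual-route check on one full-size environment: pointer doubling on
    the unreduced 2^22 successor map finds exactly the cycle states that
    the constant-percolation engine reports."""
    smap = e.build_successor_map(endmt, table4_env)
    root = smap.successors.copy()
    for _ in range(22):
        root = root[root]
    cycle_states = np.unique(root)
    free_pos = [endmt.node_index(nd) for nd in smap.free_nodes]
    env_bits = sum(v << endmt.node_index(k)
                   for k, v in table4_env.as_dict().items())
    full_states = set()
    for idx in cycle_states:
        full = env_bits
        for p, pos in enumerate(free_pos):
            full |= ((int(idx) >> p) & 1) << pos
        full_states.add(full)
    expected = {
        s
        for att in e.attractors_in_environment(wt_atlas, table4_env)
        for s in att.states
    }
    assert full_states == expected


def test_atlas_export_round_trip(wt_atlas, tmp_path):
    frame = wt_atlas.to_frame()
    # one row per (attractor, phase): 169*1 + 18*2 + 257*4
    assert len(frame) == 169 + 36 + 1028
    path = tmp_path / "atlas.csv"
    wt_atlas.to_csv(path)
    assert path.exists()
    payload = wt_atlas.to_json()
    assert '"total": 444' in payload
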