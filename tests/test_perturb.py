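"""Mutation clamps, rule-noise robustness, state-noise sensitivity, and
cell-fate transitions."""

import itertools

import numpy as np
import pytest

import endmtbn as e
from conftest import brute_force_attractors


class TestApplyMutations:
    def test_clamped_rule_is_constant(self, endmt):
        mutant = e.apply_mutations(endmt, [e.MutationSpec("DLL4", "loss")])
        rule = mutant.rule("DLL4")
        assert rule.is_constant and rule.table[0] == 0
        # environment space halves: DLL4 is no longer a source
        assert len(mutant.source_nodes) == 6

    def test_double_clamp(self, endmt):
        mutant = e.apply_mutations(endmt, [
            e.MutationSpec("ETS1", "loss"), e.MutationSpec("FLI1", "loss"),
        ])
        assert mutant.rule("ETS1").is_constant
        assert mutant.rule("FLI1").is_constant

    def test_other_rules_untouched_and_rebuild_restores(self, endmt):
        mutant = e.apply_mutations(endmt, [e.MutationSpec("SNAI1", "gain")])
        for node in endmt.nodes:
            if node == "SNAI1":
                continue
            assert np.array_equal(mutant.rule(node).table, endmt.rule(node).table)
        rebuilt = e.build_endmt_network()
        assert rebuilt.same_truth_tables(endmt)

    def test_conflicting_specs_rejected(self, endmt):
        with pytest.raises(e.NetworkError, match="conflict"):
            e.apply_mutations(endmt, [
                e.MutationSpec("SNAI1", "gain"), e.MutationSpec("SNAI1", "loss"),
            ])

    def test_clamp_soundness_in_attractors(self, endmt):
        """Every attractor state of a clamped network holds the clamp."""
        for spec in (e.MutationSpec("NOTCH", "gain"),
                     e.MutationSpec("VEGFA", "loss")):
            mutant = e.apply_mutations(endmt, [spec])
            atlas = e.enumerate_attractors(mutant)
            i = mutant.node_index(spec.node)
            for att in atlas.attractors:
                for s in att.states:
                    assert (s >> i) & 1 == spec.clamp_value


class TestDoubleMutants:
    def test_flow_mutants(self, endmt, wt_atlas):
        lo = e.double_mutant_analysis(
            endmt,
            [e.MutationSpec("ETS1", "loss"), e.MutationSpec("FLI1", "loss")],
            wild_atlas=wt_atlas,
        )
        assert lo.label_counts["EC"] == 0
        assert lo.class_counts["MCsnECs"] == 347
        assert abs(lo.class_fractions["MCsnECs"] - 0.69) < 0.005
        hi = e.double_mutant_analysis(
            endmt,
            [e.MutationSpec("ETS1", "gain"), e.MutationSpec("FLI1", "gain")],
            wild_atlas=wt_atlas,
        )
        assert hi.class_counts["MCsnECs"] == 0
        assert abs(hi.label_counts["MC"] / hi.n_attractors - 0.816) < 0.001

    def test_same_node_twice_rejected(self, endmt):
        with pytest.raises(e.NetworkError):
            e.double_mutant_analysis(endmt, [
                e.MutationSpec("ETS1", "loss"), e.MutationSpec("ETS1", "gain"),
            ])


class TestRuleFlipRobustness:
    def test_toy_exhaustive_flips_match_brute_force(self, toy3):
        """Monte Carlo over many instances visits flip outcomes whose
        attractor counts match brute-force enumeration of every possible
        single-bit flip."""
        cfg = e.ClassifierConfig(markers={"Aon": "A"})
        totals = {}
        for node in toy3.nodes:
            rule = toy3.rule(node)
            for row in range(rule.table.size):
                flipped = rule.table.copy()
                flipped[row] ^= 1
                variant = toy3.with_rules({node: e.RegulatoryFunction(
                    target=node, regulators=rule.regulators,
                    table=flipped, expression="0")})
                totals[(node, row)] = len(brute_force_attractors(variant))
        stats, counts = e.rule_flip_robustness(
            toy3, cfg, n_instances=64, seed=0)
        # total attractor count of each sampled instance must be one of
        # the exhaustively computed possibilities
        possible = set(totals.values())
        assert set(counts.sum(axis=1)) <= possible

    def test_deterministic_given_seed(self, toy3):
        cfg = e.ClassifierConfig(markers={"Aon": "A"})
        s1, c1 = e.rule_flip_robustness(toy3, cfg, n_instances=10, seed=3)
        s2, c2 = e.rule_flip_robustness(toy3, cfg, n_instances=10, seed=3)
        assert np.array_equal(c1, c2)

    def test_endmt_small_population(self, endmt):
        stats, counts = e.rule_flip_robustness(endmt, n_instances=4, seed=1)
        assert counts.shape == (4, 9)
        assert (counts.sum(axis=1) > 0).all()


class TestSensitivity:
    def test_identity_rule_analytic_values(self, endmt):
        """For an identity rule, k-bit flip sensitivity is exactly k/n in
        expectation; Monte Carlo agrees within 3 binomial standard errors."""
        rep = e.rule_sensitivity(endmt, n_samples_1bit=100_000,
                                 n_samples_kbit=20_000, seed=8, ks=(1, 15))
        n = endmt.n
        for k, m in ((1, 100_000), (15, 20_000)):
            p = k / n
            se = (p * (1 - p) / m) ** 0.5
            for src in endmt.source_nodes:
                assert abs(rep.fractions[src][k] - p) <= 3 * se + 1e-12

    def test_constant_rule_insensitive(self, endmt):
        mutant = e.apply_mutations(endmt, [e.MutationSpec("SNAI1", "gain")])
        rep = e.rule_sensitivity(mutant, n_samples_1bit=20_000,
                                 n_samples_kbit=5_000, seed=9, ks=(1, 5))
        assert rep.fractions["SNAI1"][1] == 0.0
        assert rep.fractions["SNAI1"][5] == 0.0

    def test_invalid_k_rejected(self, endmt):
        with pytest.raises(ValueError):
            e.rule_sensitivity(endmt, ks=(0,))


@pytest.fixture(scope="module")
def transitions():
    net = e.build_endmt_network()
    atlas = e.enumerate_attractors(net)
    records, matrix = e.perturbation_transitions(net, atlas)
    return net, atlas, records, matrix


class TestTransitions:
    def test_noop_pattern_returns_to_source(self, transitions):
        """A pattern equal to the attractor's own bits on the perturbed
        nodes leaves the attractor unchanged."""
        net, atlas, _, _ = transitions
        positions = [net.node_index(nd) for nd in e.DEFAULT_PERTURBATION_NODES]
        rng = np.random.default_rng(10)
        for aid in rng.choice(len(atlas.attractors), size=40, replace=False):
            att = atlas.attractors[aid]
            start = att.states[0]
            resolved = atlas.resolver.resolve(
                np.array([start], dtype=np.uint64))[0]
            assert resolved == aid
            # overwriting with its own bits is the identity
            own = 0
            for pos in positions:
                own |= start & (1 << pos)
            mask = sum(1 << p for p in positions)
            perturbed = (start & ~mask) | own
            assert perturbed == start

    def test_tip_classes_never_reach_full_transition(self, transitions):
        """No perturbation sends a Tip-class attractor to the
        mesenchymal-not-endothelial class (Tip cells cannot undergo full
        EndMT directly)."""
        _, _, _, matrix = transitions
        assert matrix.loc["nMCTip", "MCsnECs"] == 0
        assert matrix.loc["MCTip", "MCsnECs"] == 0

    def test_phalanx_to_full_transition_requires_identity_loss(self, transitions):
        """Patterns driving Phalanx attractors into the full transition
        all silence FLI1, GATA2, HIF1a, and VEGFA."""
        _, _, records, matrix = transitions
        assert matrix.loc["Phalanx", "MCsnECs"] > 0
        rec = next(r for r in records
                   if r.source_class == "Phalanx" and r.dest_class == "MCsnECs")
        assert {"FLI1", "GATA2", "HIF1a", "VEGFA"} <= set(rec.always_inactive)

    def test_modes_agree_on_pattern_space(self, endmt, wt_atlas):
        _, m_first = e.perturbation_transitions(endmt, wt_atlas, mode="first")
        _, m_all = e.perturbation_transitions(endmt, wt_atlas, mode="all")
        assert (m_first.values <= m_all.values).all()
        assert m_first.values.max() <= 1024

    def test_unknown_perturb_node_rejected(self, endmt, wt_atlas):
        with pytest.raises(e.NetworkError):
            e.perturbation_transitions(endmt, wt_atlas,
                                       perturb_nodes=("NOSUCH",))


class TestSingleMutationScanSubset:
    def test_subset_profiles(self, endmt, wt_atlas):
        """Spot-check the scan on a small node subset: clamps known to be
        absorbed keep the wild-type profile, and FLI1 loss abolishes the
        endothelial classes."""
        reports, summary = e.scan_single_mutations(
            endmt, atlas=wt_atlas, nodes=["DLL4", "SMAD1", "FLI1"])
        by_name = {r.name: r for r in reports}
        assert by_name["DLL4-"].unchanged
        assert by_name["SMAD1-"].unchanged
        assert by_name["SMAD1+"].unchanged
        fli = by_name["FLI1-"]
        assert not fli.unchanged
        assert {"Phalanx", "nMCTip", "MCTip", "nMCStalk", "MCStalk",
                "EConly", "MCEConly"} <= fli.lost_classes
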