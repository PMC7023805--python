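import numpy as np
import pytest

from domevol import (DomainArrangement, PhyloTree, SpeciesAnnotation, TriState,
                     ValidationError, dollo_reconstruct, fitch_reconstruct,
                     reconstruct_all)

from .oracles import (count_changes, dollo_min_losses, enumerate_topologies,
                      fitch_min_changes, gains_and_losses)

A = DomainArrangement.parse


def leaf_sets(tree, present):
    return {leaf.label: ({"x"} if leaf.label in present else set())
            for leaf in tree.leaves()}


class TestFitch:
    def test_split_character_resolved_by_root_rule(self, quartet_tree):
        t = quartet_tree
        for rule, expected_root in [("absent", TriState.ABSENT),
                                    ("present", TriState.PRESENT)]:
            m = fitch_reconstruct(t, leaf_sets(t, {"L1", "L2"}), ["x"],
                                  root_unknown=rule)
            inner12 = next(n for n in t.preorder()
                           if t.subtree_leaves(n.id) == {"L1", "L2"})
            inner34 = next(n for n in t.preorder()
                           if t.subtree_leaves(n.id) == {"L3", "L4"})
            assert m.state(inner12.id, "x") == TriState.PRESENT
            assert m.state(inner34.id, "x") == TriState.ABSENT
            assert m.state(t.root.id, "x") == expected_root

    def test_uniform_presence_everywhere(self, quartet_tree):
        m = fitch_reconstruct(quartet_tree,
                              leaf_sets(quartet_tree, {"L1", "L2", "L3", "L4"}),
                              ["x"])
        assert all(m.state(n.id, "x") == TriState.PRESENT
                   for n in quartet_tree.preorder())

    def test_autapomorphy_stays_at_the_leaf(self, quartet_tree):
        m = fitch_reconstruct(quartet_tree, leaf_sets(quartet_tree, {"L1"}), ["x"])
        for node in quartet_tree.preorder():
            expected = TriState.PRESENT if node.id == "L1" else TriState.ABSENT
            assert m.state(node.id, "x") == expected

    def test_missing_leaf_state_is_an_error(self, quartet_tree):
        with pytest.raises(ValidationError, match="L4"):
            fitch_reconstruct(quartet_tree,
                              {"L1": {"x"}, "L2": set(), "L3": set()}, ["x"])

    def test_matches_minimum_change_oracle_on_random_cases(self):
        rng = np.random.default_rng(42)
        labels = ["a", "b", "c", "d", "e"]
        topologies = enumerate_topologies(labels)
        picks = rng.choice(len(topologies), size=12, replace=False)
        for ti in picks:
            tree = PhyloTree.from_nested(topologies[ti])
            for _ in range(4):
                present = {l for l in labels if rng.integers(2)}
                m = fitch_reconstruct(tree, leaf_sets(tree, present), ["x"])
                state = {n.id: int(m.state(n.id, "x")) for n in tree.preorder()}
                assert set(state.values()) <= {0, 1}
                leaf_state = {l: (1 if l in present else 0) for l in labels}
                assert count_changes(tree, state) == fitch_min_changes(tree, leaf_state)


class TestDollo:
    def test_scattered_presence_gains_at_root_with_two_losses(self, quartet_tree):
        t = quartet_tree
        m, gains = dollo_reconstruct(t, leaf_sets(t, {"L1", "L3"}), ["x"])
        assert gains["x"] == t.root.id
        for node in t.preorder():
            expected = TriState.ABSENT if node.id in {"L2", "L4"} else TriState.PRESENT
            assert m.state(node.id, "x") == expected

    def test_clade_restricted_presence_gains_at_mrca(self, quartet_tree):
        t = quartet_tree
        m, gains = dollo_reconstruct(t, leaf_sets(t, {"L1", "L2"}), ["x"])
        inner12 = next(n for n in t.preorder()
                       if t.subtree_leaves(n.id) == {"L1", "L2"})
        assert gains["x"] == inner12.id
        assert m.state(t.root.id, "x") == TriState.ABSENT
        assert m.state(inner12.id, "x") == TriState.PRESENT

    def test_absent_character_has_no_gain(self, quartet_tree):
        m, gains = dollo_reconstruct(quartet_tree, leaf_sets(quartet_tree, set()),
                                     ["x"])
        assert gains["x"] is None
        assert all(m.state(n.id, "x") == TriState.ABSENT
                   for n in quartet_tree.preorder())

    def test_matches_minimum_loss_oracle_on_random_cases(self):
        rng = np.random.default_rng(7)
        labels = ["a", "b", "c", "d", "e"]
        topologies = enumerate_topologies(labels)
        picks = rng.choice(len(topologies), size=12, replace=False)
        for ti in picks:
            tree = PhyloTree.from_nested(topologies[ti])
            for _ in range(4):
                present = {l for l in labels if rng.integers(2)}
                m, _ = dollo_reconstruct(tree, leaf_sets(tree, present), ["x"])
                state = {n.id: int(m.state(n.id, "x")) for n in tree.preorder()}
                gains, losses = gains_and_losses(tree, state)
                leaf_state = {l: (1 if l in present else 0) for l in labels}
                assert gains == (1 if present else 0)
                assert losses == dollo_min_losses(tree, leaf_state)


class TestReconstructAll:
    def test_shared_repertoire_present_everywhere(self):
        tree = PhyloTree.from_newick("(sp1,sp2);")
        anns = [SpeciesAnnotation(s, {"p": A("A-B")}) for s in ("sp1", "sp2")]
        recon = reconstruct_all(tree, anns)
        for node in tree.preorder():
            assert A("A-B") in recon.arrangement_set(node.id)
            assert recon.dollo.state(node.id, "A") == TriState.PRESENT
            assert recon.dollo.state(node.id, "B") == TriState.PRESENT

    def test_private_single_domains_gain_at_their_leaves(self):
        tree = PhyloTree.from_newick("(sp1,sp2);")
        anns = [SpeciesAnnotation("sp1", {"p": A("A")}),
                SpeciesAnnotation("sp2", {"p": A("B")})]
        recon = reconstruct_all(tree, anns)
        assert recon.dollo_gains == {"A": "sp1", "B": "sp2"}
        # default root rule resolves the split arrangement characters absent
        assert len(recon.arrangement_set(tree.root.id)) == 0

    def test_empty_repertoire_leaf_is_allowed(self, quartet_tree):
        anns = [SpeciesAnnotation(s, {"p": A("A")}) for s in ("L1", "L2", "L3")]
        anns.append(SpeciesAnnotation("L4", {}))
        recon = reconstruct_all(quartet_tree, anns)
        assert len(recon.arrangement_set("L4")) == 0
        assert A("A") in recon.arrangement_set(quartet_tree.root.id)

    def test_species_mismatch_names_the_culprits(self, quartet_tree):
        anns = [SpeciesAnnotation(s, {"p": A("A")}) for s in ("L1", "L2", "L3")]
        with pytest.raises(ValidationError, match="L4"):
            reconstruct_all(quartet_tree, anns)

    def test_deterministic_under_input_reordering(self, quartet_tree):
        anns = [
            SpeciesAnnotation("L1", {"p1": A("A-B"), "p2": A("C")}),
            SpeciesAnnotation("L2", {"p1": A("C")}),
            SpeciesAnnotation("L3", {"p1": A("A-B-C")}),
            SpeciesAnnotation("L4", {"p1": A("B")}),
        ]
        r1 = reconstruct_all(quartet_tree, anns)
        r2 = reconstruct_all(quartet_tree, list(reversed(anns)))
        assert np.array_equal(r1.fitch.states, r2.fitch.states)
        assert np.array_equal(r1.dollo.states, r2.dollo.states)
        assert r1.dollo_gains == r2.dollo_gains
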