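import pytest

from domevol import (ArrangementSet, CandidateEvent, ChangeKind,
                     DomainArrangement, EventType, SolutionType,
                     SpeciesAnnotation, ValidationError, classify, explain_gain,
                     explain_loss, infer_events, node_changes, reconstruct_all)

A = DomainArrangement.parse


def aset(*texts):
    return ArrangementSet(A(t) for t in texts)


class TestNodeChanges:
    def test_gain_only(self):
        gained, lost = node_changes(aset("A", "B-C"), aset("A", "B-C", "A-B-C"))
        assert gained == {A("A-B-C")} and lost == frozenset()

    def test_identical_sets(self):
        gained, lost = node_changes(aset("A"), aset("A"))
        assert gained == frozenset() and lost == frozenset()

    def test_fission_like_diff(self):
        gained, lost = node_changes(aset("A-B"), aset("A", "B"))
        assert gained == {A("A"), A("B")} and lost == {A("A-B")}


class TestExplainGain:
    def test_two_fusion_routes_non_ambiguous(self):
        """ABC from {A, AB, BC, C}: exactly the routes A+BC and AB+C."""
        cands = explain_gain(A("A-B-C"), aset("A", "A-B", "B-C", "C"),
                             aset("A", "A-B", "B-C", "C", "A-B-C"), {}, "n")
        assert {(c.event_type, tuple(map(str, c.precursors))) for c in cands} == {
            (EventType.FUSION, ("A", "B-C")),
            (EventType.FUSION, ("A-B", "C")),
        }
        assert classify(cands) == SolutionType.NON_AMBIGUOUS

    def test_junction_merge_variant_adds_shared_boundary_route(self):
        cands = explain_gain(A("A-B-C"), aset("A", "A-B", "B-C", "C"),
                             aset("A-B-C"), {}, "n", junction_merge=True)
        routes = {tuple(map(str, c.precursors)) for c in cands}
        assert ("A-B", "B-C") in routes
        assert len(cands) == 3

    def test_terminal_loss_vs_fusion_ambiguous(self):
        """ABC from {ABCD, AB, C} with D leaving no trace: ABC-D / AB+C."""
        cands = explain_gain(A("A-B-C"), aset("A-B-C-D", "A-B", "C"),
                             aset("A-B-C", "A-B", "C"), {}, "n")
        by_type = {c.event_type for c in cands}
        assert by_type == {EventType.TERMINAL_LOSS, EventType.FUSION}
        assert len(cands) == 2
        assert classify(cands) == SolutionType.AMBIGUOUS

    def test_persisting_complement_makes_it_fission_not_terminal_loss(self):
        cands = explain_gain(A("A-B-C"), aset("A-B-C-D"),
                             aset("A-B-C", "D"), {}, "n")
        assert [c.event_type for c in cands] == [EventType.FISSION]

    def test_fission_and_terminal_loss_never_share_a_precursor(self):
        # ABCAB: AB is both a proper prefix and suffix; only the suffix
        # complement ABC persists in the child.
        cands = explain_gain(A("A-B"), aset("A-B-C-A-B", "Z"),
                             aset("A-B", "A-B-C"), {}, "n")
        assert {c.event_type for c in cands} == {EventType.FISSION}

    def test_terminal_emergence_requires_dollo_gain_here(self):
        parent = aset("A-B")
        child = aset("A-B", "A-B-N")
        with_gate = explain_gain(A("A-B-N"), parent, child, {"N": "n"}, "n")
        assert [c.event_type for c in with_gate] == [EventType.TERMINAL_EMERGENCE]
        elsewhere = explain_gain(A("A-B-N"), parent, child, {"N": "other"}, "n")
        assert elsewhere == []

    def test_single_emergence_gated_by_dollo(self):
        cands = explain_gain(A("N"), aset("A"), aset("A", "N"), {"N": "n"}, "n")
        assert [c.event_type for c in cands] == [EventType.SINGLE_EMERGENCE]
        assert classify(cands) == SolutionType.EXACT
        assert explain_gain(A("N"), aset("A"), aset("A", "N"), {"N": "m"}, "n") == []

    def test_gain_already_in_parent_is_a_precondition_error(self):
        with pytest.raises(ValidationError):
            explain_gain(A("A"), aset("A"), aset("A"), {}, "n")

    def test_unique_fusion_replays_exactly(self):
        from domevol import concat_collapse
        cands = explain_gain(A("A-B-C"), aset("A", "B-C"),
                             aset("A", "B-C", "A-B-C"), {}, "n")
        assert classify(cands) == SolutionType.EXACT
        (cand,) = cands
        assert concat_collapse(*cand.precursors) == A("A-B-C")


class TestExplainLoss:
    def test_complete_single_domain_loss(self):
        cands = explain_loss(A("A"), aset("A", "B-C"), aset("B-C"))
        assert [c.event_type for c in cands] == [EventType.SINGLE_LOSS]

    def test_domain_persisting_elsewhere_is_not_a_single_loss(self):
        assert explain_loss(A("A"), aset("A", "A-B"), aset("A-B")) == []

    def test_multi_domain_loss_is_unclassified(self):
        assert explain_loss(A("A-B-C"), aset("A-B-C"), aset("Z")) == []


class TestClassify:
    @pytest.mark.parametrize(
        "types, expected",
        [
            ([], SolutionType.COMPLEX),
            ([EventType.FUSION], SolutionType.EXACT),
            ([EventType.FUSION, EventType.FUSION], SolutionType.NON_AMBIGUOUS),
            ([EventType.TERMINAL_LOSS, EventType.FUSION], SolutionType.AMBIGUOUS),
        ],
    )
    def test_rules(self, types, expected):
        cands = [CandidateEvent(t, (A("A"),), A("A"), str(i))
                 for i, t in enumerate(types)]
        assert classify(cands) == expected


class TestInferEvents:
    def test_no_changes_yields_no_records(self, quartet_tree):
        anns = [SpeciesAnnotation(s, {"p": A("A-B")})
                for s in ("L1", "L2", "L3", "L4")]
        recon = reconstruct_all(quartet_tree, anns)
        assert infer_events(recon) == []

    def test_fusion_gain_at_a_leaf(self, quartet_tree):
        base = {"p1": A("A"), "p2": A("B-C")}
        anns = [SpeciesAnnotation("L1", {**base, "p3": A("A-B-C")})]
        anns += [SpeciesAnnotation(s, dict(base)) for s in ("L2", "L3", "L4")]
        recon = reconstruct_all(quartet_tree, anns)
        records = infer_events(recon)
        assert len(records) == 1
        (r,) = records
        assert (r.node_id, r.change_kind, r.solution, r.resolved_type) == \
            ("L1", ChangeKind.GAINED, SolutionType.EXACT, EventType.FUSION)

    def test_single_emergence_and_loss_at_one_node(self, quartet_tree):
        others = {"p1": A("A"), "p2": A("C")}
        anns = [SpeciesAnnotation("L1", {"p1": A("A"), "p2": A("D")})]
        anns += [SpeciesAnnotation(s, dict(others)) for s in ("L2", "L3", "L4")]
        recon = reconstruct_all(quartet_tree, anns)
        records = infer_events(recon)
        by_kind = {(r.change_kind, str(r.arrangement)): r for r in records}
        gain = by_kind[(ChangeKind.GAINED, "D")]
        loss = by_kind[(ChangeKind.LOST, "C")]
        assert gain.solution == SolutionType.EXACT
        assert gain.resolved_type == EventType.SINGLE_EMERGENCE
        assert loss.solution == SolutionType.EXACT
        assert loss.resolved_type == EventType.SINGLE_LOSS
        assert {r.node_id for r in records} == {"L1"}

    def test_excluded_nodes_are_skipped(self, quartet_tree):
        base = {"p1": A("A"), "p2": A("B-C")}
        anns = [SpeciesAnnotation("L1", {**base, "p3": A("A-B-C")})]
        anns += [SpeciesAnnotation(s, dict(base)) for s in ("L2", "L3", "L4")]
        recon = reconstruct_all(quartet_tree, anns)
        assert infer_events(recon, excluded_nodes=frozenset({"L1"})) == []

    def test_records_are_deterministically_ordered(self, quartet_tree):
        anns = [
            SpeciesAnnotation("L1", {"p1": A("A"), "p2": A("B"), "p3": A("C")}),
            SpeciesAnnotation("L2", {"p1": A("A")}),
            SpeciesAnnotation("L3", {"p1": A("A")}),
            SpeciesAnnotation("L4", {"p1": A("A")}),
        ]
        recon = reconstruct_all(quartet_tree, anns)
        r1 = infer_events(recon)
        r2 = infer_events(recon)
        assert r1 == r2
        l1 = [str(r.arrangement) for r in r1 if r.node_id == "L1"]
        assert l1 == sorted(l1)
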