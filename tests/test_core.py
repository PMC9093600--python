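"""The pruning cascade: local rules, phase machine, trace, properties."""

import json
import random

import pytest

import sgp
from sgp import (
    InspectionContext,
    Phase,
    PruneError,
    SynthesisGraph,
    UndesirableSet,
    fixture,
    inspect_substance,
    prune,
    undefined_reactions,
)

from conftest import ALL_FIXTURES, draw_small, shuffled


class TestUndefinedReactions:
    def test_walkthrough_initial_deletion(self):
        graph, _ = fixture("fig1")
        assert undefined_reactions(graph, {"H", "I"}) == {"3", "5", "6"}

    def test_empty_deletion_set(self):
        graph, _ = fixture("fig1")
        assert undefined_reactions(graph, set()) == set()

    def test_cyclic_graph_counts_producers_and_consumers(self):
        # deleting a substance undefines the reactions it feeds AND the
        # reactions producing it
        graph, _ = fixture("case6")
        assert undefined_reactions(graph, {"A"}) == {"1", "5", "6"}

    def test_reaction_id_rejected(self):
        graph, _ = fixture("fig1")
        with pytest.raises(PruneError, match="reaction node"):
            undefined_reactions(graph, {"3"})


def after_reaction_deletion(name: str, reactions: set[str]) -> SynthesisGraph:
    """Fixture graph with a batch of reactions (and nothing else) removed."""
    graph, _ = fixture(name)
    g = graph.copy()
    g.remove_nodes(reactions)
    return g


class TestInspectSubstance:
    def test_substance_keeping_another_child_survives(self):
        # E lost consuming reaction 3 but still feeds reaction 4
        g = after_reaction_deletion("fig1", {"3", "5", "6"})
        assert inspect_substance(InspectionContext("E", lost_children=1), g) == "keep"

    def test_intermediate_without_parent_is_deleted(self):
        # M lost its only producer and is not inventory-available
        g = after_reaction_deletion("fig1", {"3", "5", "6"})
        assert inspect_substance(InspectionContext("M", lost_parents=1), g) == "delete"

    def test_childless_substance_is_deleted(self):
        # G lost its only consumer: a dead end even though it is a
        # starting material
        g = after_reaction_deletion("fig1", {"3", "5", "6"})
        assert inspect_substance(InspectionContext("G", lost_children=1), g) == "delete"

    def test_starting_material_without_parent_survives(self):
        # cyclic case: E's in-degree drops to zero but it is available
        # from the inventory
        g = after_reaction_deletion("case6", {"1", "5", "6"})
        assert inspect_substance(InspectionContext("E", lost_parents=1), g) == "keep"

    def test_target_keeping_another_parent_survives(self):
        g = after_reaction_deletion("fig1", {"8", "9"})
        assert inspect_substance(InspectionContext("T", lost_parents=1), g) == "keep"

    def test_target_exempt_from_child_loss(self):
        # a target consumed by some deleted reaction must not be removed
        # for having out-degree zero: a route terminus has no consumers
        g = SynthesisGraph()
        g.add_substance("S", is_starting_material=True)
        g.add_substance("T", is_target=True)
        g.add_reaction("r")
        g.add_edge("S", "r")
        g.add_edge("r", "T")
        assert inspect_substance(InspectionContext("T", lost_children=1), g) == "keep"

    def test_dual_role_loss_either_criterion_suffices(self):
        # X fed one deleted reaction and was produced by another; it keeps
        # a child but has no parent left -> parent-loss criterion fires
        g = SynthesisGraph()
        g.add_substance("X")
        g.add_substance("T", is_target=True)
        g.add_reaction("r_keep")
        g.add_edge("X", "r_keep")
        g.add_edge("r_keep", "T")
        ctx = InspectionContext("X", lost_children=1, lost_parents=1)
        assert inspect_substance(ctx, g) == "delete"

    def test_context_requires_a_loss(self):
        with pytest.raises(PruneError):
            InspectionContext("X", lost_children=0, lost_parents=0)


class TestPruneWalkthrough:
    def test_walkthrough_step_sequence(self):
        graph, undesirable = fixture("fig1")
        result = prune(graph, undesirable)
        phases = [(s.index, s.phase, s.deleted, s.newly_marked_deletion) for s in result.trace]
        assert phases == [
            (1, Phase.MARK_INITIAL, set(), {"H", "I"}),
            (2, Phase.DELETE_SUBSTANCES_MARK_REACTIONS, {"H", "I"}, {"3", "5", "6"}),
            (3, Phase.MARK_INSPECTION, set(), set()),
            (4, Phase.DELETE_REACTIONS_EVALUATE, {"3", "5", "6"}, {"G", "M", "N"}),
            (5, Phase.DELETE_SUBSTANCES_MARK_REACTIONS, {"G", "M", "N"}, {"8", "9"}),
            (6, Phase.MARK_INSPECTION, set(), set()),
            (7, Phase.DELETE_REACTIONS_EVALUATE, {"8", "9"}, {"L"}),
            (8, Phase.DELETE_SUBSTANCES_MARK_REACTIONS, {"L"}, set()),
        ]
        assert result.trace[2].newly_marked_inspection == {"E", "G", "J", "M", "N"}
        assert result.trace[3].unmarked == {"E", "J"}
        assert result.trace[5].newly_marked_inspection == {"L", "O", "T"}
        assert result.trace[6].unmarked == {"O", "T"}
        assert result.step_count == 8
        assert not result.is_empty

    def test_output_is_the_single_surviving_route(self):
        graph, undesirable = fixture("fig1")
        result = prune(graph, undesirable)
        assert result.graph.substances == {"A", "B", "C", "D", "E", "F", "J", "K", "O", "T"}
        assert result.graph.reactions == {"1", "2", "4", "7", "10"}
        assert sgp.count_routes(result.graph) == 1

    def test_deleted_sets_across_steps_are_disjoint(self):
        graph, undesirable = fixture("fig1")
        result = prune(graph, undesirable)
        seen = set()
        for step in result.trace:
            assert not (step.deleted & seen)
            seen |= step.deleted

    def test_input_graph_not_mutated(self):
        graph, undesirable = fixture("fig1")
        before = graph.copy()
        prune(graph, undesirable)
        assert graph == before


class TestPruneContracts:
    def test_empty_undesirable_set_is_identity(self):
        for name in ("fig1", "case2", "case6", "usecase1"):
            graph, _ = fixture(name)
            result = prune(graph, UndesirableSet())
            assert result.graph == graph
            assert result.step_count == 1

    def test_unknown_id_ignored_when_lenient(self):
        graph, _ = fixture("fig1")
        result = prune(graph, UndesirableSet({"nonexistent"}))
        assert result.graph == graph
        assert any("nonexistent" in w for w in result.warnings)

    def test_unknown_id_error_when_strict(self):
        graph, _ = fixture("fig1")
        with pytest.raises(PruneError, match="not present"):
            prune(graph, UndesirableSet({"nonexistent"}), strict=True)

    def test_reaction_id_always_an_error(self):
        graph, _ = fixture("fig1")
        with pytest.raises(PruneError, match="reaction node"):
            prune(graph, UndesirableSet({"3"}))

    def test_missing_target_is_an_error(self):
        g = SynthesisGraph()
        g.add_substance("S", is_starting_material=True)
        g.add_substance("P")
        g.add_reaction("r")
        g.add_edge("S", "r")
        g.add_edge("r", "P")
        with pytest.raises(sgp.GraphModelError, match="targets"):
            prune(g, UndesirableSet({"S"}))

    def test_undesirable_target_empties_graph_with_warning(self):
        graph, _ = fixture("fig1")
        result = prune(graph, UndesirableSet({"T"}))
        assert result.is_empty
        assert any("target" in w for w in result.warnings)

    def test_invalid_graph_rejected(self):
        g = SynthesisGraph()
        g.add_substance("A", is_starting_material=True)
        g.add_substance("T", is_target=True)
        g.nx.add_edge("A", "T")
        with pytest.raises(PruneError, match="BIPARTITE"):
            prune(g, UndesirableSet())


class TestTraceSerialization:
    def test_json_document(self):
        graph, undesirable = fixture("fig1")
        result = prune(graph, undesirable)
        doc = json.loads(result.trace_json())
        assert [s["index"] for s in doc] == list(range(1, 9))
        assert doc[1]["deleted"] == ["H", "I"]
        assert doc[1]["phase"] == "delete_substances_mark_reactions"

    def test_line_log(self):
        graph, undesirable = fixture("fig1")
        lines = prune(graph, undesirable).trace_lines()
        assert len(lines) == 8
        assert lines[0].startswith("step 1 [mark_initial]")
        assert "marked for deletion: H,I" in lines[0]


class TestPruneProperties:
    @pytest.mark.parametrize("name", ALL_FIXTURES)
    def test_order_invariance_on_fixtures(self, name):
        graph, undesirable = fixture(name)
        baseline = prune(graph, undesirable)
        for seed in range(10):
            result = prune(shuffled(graph, seed), undesirable)
            assert result.graph == baseline.graph
            assert result.deleted_nodes == baseline.deleted_nodes

    @pytest.mark.parametrize("name", ALL_FIXTURES)
    def test_termination_bound_on_fixtures(self, name):
        graph, undesirable = fixture(name)
        result = prune(graph, undesirable)
        assert result.step_count <= 3 * len(graph) + 1

    @pytest.mark.parametrize("name", ALL_FIXTURES)
    def test_idempotence_on_fixtures(self, name):
        graph, undesirable = fixture(name)
        once = prune(graph, undesirable).graph
        again = prune(once, UndesirableSet()) if once.targets else None
        if again is not None:
            assert again.graph == once

    @pytest.mark.parametrize("cycle_prob", [0.0, 0.2])
    def test_containment_of_sequential_pruning(self, cycle_prob):
        # pruning I1 then I2 equals pruning I1 ∪ I2 in one pass
        rng = random.Random(int(cycle_prob * 10) + 7)
        checked = 0
        for seed in range(100):
            g = draw_small(rng, seed, cycle_prob)
            subs = sorted(g.substances - {g.target})
            i1 = set(rng.sample(subs, min(len(subs), rng.randint(0, 2))))
            i2 = set(rng.sample(subs, min(len(subs), rng.randint(0, 2))))
            joint = prune(g, UndesirableSet(i1 | i2)).graph
            first = prune(g, UndesirableSet(i1)).graph
            if not first.targets:
                continue  # cascade reached the target: nothing left to prune
            second = prune(first, UndesirableSet(i2 & first.substances)).graph
            assert second == joint
            checked += 1
        assert checked >= 50
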