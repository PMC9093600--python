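"""The synthesis-graph pruning cascade.

Given a synthesis graph ``G`` and a set ``I`` of undesirable substances
(toxic, unstable, unavailable, ...), pruning removes every synthesis route
that touches ``I`` while leaving all other routes intact.  The cascade is
driven by a purely local rule set:

* a reaction adjacent to a deleted substance — whether the substance was a
  reactant or a product — becomes *undefined* and must itself be deleted;
* a substance that lost a consuming reaction ("child") and is now without
  any child is a dead end and is deleted, unless it is the target molecule;
* a substance that lost a producing reaction ("parent"), is now without any
  parent and is not available from the inventory can no longer be made and
  is deleted.

Deletions are applied in phase-synchronised batches until a batch marks
nothing further, or the graph empties.  Each phase is recorded as one
:class:`PruneStep` so the run can be audited step by step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from .graph_model import SynthesisGraph, validate

log = logging.getLogger(__name__)


class PruneError(ValueError):
    """Invalid input to the pruning cascade."""


class Phase(str, Enum):
    """The phase a trace step belongs to.

    ``MARK_INITIAL`` marks the undesirable substances; then the cascade
    cycles through substance deletion + reaction marking, inspection
    marking, and reaction deletion + inspection evaluation.
    """

    MARK_INITIAL = "mark_initial"
    DELETE_SUBSTANCES_MARK_REACTIONS = "delete_substances_mark_reactions"
    MARK_INSPECTION = "mark_inspection"
    DELETE_REACTIONS_EVALUATE = "delete_reactions_evaluate"


@dataclass(frozen=True)
class UndesirableSet:
    """Substance identifiers to be eliminated from every route."""

    ids: frozenset[str]

    def __init__(self, ids: Iterable[str] = ()):
        object.__setattr__(self, "ids", frozenset(ids))

    def __iter__(self):
        return iter(sorted(self.ids))

    def __len__(self):
        return len(self.ids)

    def __contains__(self, item: str) -> bool:
        return item in self.ids


@dataclass(frozen=True)
class InspectionContext:
    """What a substance lost in the reaction-deletion batch under evaluation.

    ``lost_children`` counts just-deleted reactions that consumed the
    substance, ``lost_parents`` counts just-deleted reactions that produced
    it.  A substance that fed one deleted reaction and was produced by
    another has both counts positive and both elimination criteria are
    assessed; either one suffices for deletion.
    """

    substance_id: str
    lost_children: int = 0
    lost_parents: int = 0

    def __post_init__(self):
        if self.lost_children + self.lost_parents < 1:
            raise PruneError(
                f"substance {self.substance_id!r} is under inspection but lost no adjacent reaction"
            )


@dataclass
class PruneStep:
    """One phase-level step of the cascade, at walkthrough granularity."""

    index: int
    phase: Phase
    deleted: set[str] = field(default_factory=set)
    newly_marked_deletion: set[str] = field(default_factory=set)
    newly_marked_inspection: set[str] = field(default_factory=set)
    unmarked: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "phase": self.phase.value,
            "deleted": sorted(self.deleted),
            "newly_marked_deletion": sorted(self.newly_marked_deletion),
            "newly_marked_inspection": sorted(self.newly_marked_inspection),
            "unmarked": sorted(self.unmarked),
        }


@dataclass
class PruneResult:
    """Pruned graph plus the ordered phase-level trace."""

    graph: SynthesisGraph
    trace: list[PruneStep]
    warnings: list[str] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return len(self.graph) == 0

    @property
    def step_count(self) -> int:
        return self.trace[-1].index if self.trace else 0

    @property
    def deleted_nodes(self) -> set[str]:
        out: set[str] = set()
        for step in self.trace:
            out |= step.deleted
        return out

    def trace_json(self) -> str:
        return json.dumps([s.to_dict() for s in self.trace], indent=2)

    def trace_lines(self) -> list[str]:
        """Line-oriented log of the trace, one phase per line."""
        lines = []
        for s in self.trace:
            parts = [f"step {s.index} [{s.phase.value}]"]
            if s.deleted:
                parts.append("deleted: " + ",".join(sorted(s.deleted)))
            if s.newly_marked_deletion:
                parts.append("marked for deletion: " + ",".join(sorted(s.newly_marked_deletion)))
            if s.newly_marked_inspection:
                parts.append("marked for inspection: " + ",".join(sorted(s.newly_marked_inspection)))
            if s.unmarked:
                parts.append("unmarked: " + ",".join(sorted(s.unmarked)))
            lines.append("; ".join(parts))
        return lines


# ---------------------------------------------------------------------------
# Local rules
# ---------------------------------------------------------------------------


def undefined_reactions(graph: SynthesisGraph, deleted_substances: Iterable[str]) -> set[str]:
    """Reactions losing their definition when ``deleted_substances`` go away.

    A reaction is undefined as soon as any adjacent substance is deleted,
    regardless of whether that substance was a reactant or a product: a
    reaction without one of its inputs cannot be run, and a reaction whose
    product is forbidden must not be run.
    """
    out: set[str] = set()
    for s in deleted_substances:
        if s not in graph:
            raise PruneError(f"id {s!r} does not name a node of the graph")
        if not graph.is_substance(s):
            raise PruneError(f"id {s!r} names a reaction node, not a substance")
        out |= graph.children(s)
        out |= graph.parents(s)
    return out


def inspect_substance(ctx: InspectionContext, graph: SynthesisGraph) -> str:
    """Apply the elimination criteria to one inspected substance.

    ``graph`` must reflect the state *after* the triggering reaction batch
    was deleted.  Returns ``"delete"`` or ``"keep"``.

    Child-loss: the substance lost a consumer and now has out-degree zero —
    it leads nowhere, delete it (the designated target is exempt: a route
    terminus has no consumers by construction).  Parent-loss: the substance
    lost a producer, now has in-degree zero and is not available from the
    inventory — it can no longer be obtained, delete it.  A substance that
    lost reactions in both roles is deleted if either criterion holds.
    """
    s = ctx.substance_id
    if s not in graph or not graph.is_substance(s):
        raise PruneError(f"id {s!r} does not name a substance of the graph")
    data = graph.nx.nodes[s]
    if ctx.lost_children >= 1 and graph.nx.out_degree(s) == 0 and not data.get("is_target"):
        return "delete"
    if ctx.lost_parents >= 1 and graph.nx.in_degree(s) == 0 and not data.get("is_starting_material"):
        return "delete"
    return "keep"


# ---------------------------------------------------------------------------
# The cascade
# ---------------------------------------------------------------------------


def prune(
    graph: SynthesisGraph,
    undesirable: UndesirableSet | Iterable[str],
    strict: bool = False,
) -> PruneResult:
    """Prune ``graph`` so that no synthesis route intersects ``undesirable``.

    The input graph must pass validation and designate exactly one target.
    Undesirable ids that are absent from the graph are ignored with a
    warning (they routinely come from organisation-wide block lists), or
    rejected when ``strict`` is true; an id naming a reaction node is
    always an error.  The input graph is never mutated.

    Step semantics (matching the phase granularity of the worked
    walkthrough): step 1 marks every undesirable substance for deletion;
    then each cycle spends one step deleting marked substances and marking
    their adjacent reactions, one step marking substances adjacent to those
    reactions for inspection, and one step deleting the reactions and
    evaluating every inspected substance with :func:`inspect_substance`.
    The cascade stops after a deletion step that leaves nothing marked, or
    when the graph empties.
    """
    if not isinstance(undesirable, UndesirableSet):
        undesirable = UndesirableSet(undesirable)
    report = validate(graph)
    if not report.ok:
        raise PruneError(
            "input graph fails validation: "
            + "; ".join(f"{v.code}[{v.ref}]" for v in report.violations)
        )
    target = graph.target  # raises unless exactly one designated target

    warnings: list[str] = []
    present: set[str] = set()
    for uid in undesirable:
        if uid in graph:
            if not graph.is_substance(uid):
                raise PruneError(f"undesirable id {uid!r} names a reaction node")
            present.add(uid)
        else:
            msg = f"undesirable id {uid!r} not present in graph"
            if strict:
                raise PruneError(msg)
            log.warning("%s; ignored", msg)
            warnings.append(msg)
    if target in present:
        msg = f"target molecule {target!r} is itself undesirable; pruning will empty the graph"
        log.warning(msg)
        warnings.append(msg)

    g = graph.copy()
    trace: list[PruneStep] = []

    def step(phase: Phase, **kw) -> PruneStep:
        st = PruneStep(index=len(trace) + 1, phase=phase, **kw)
        trace.append(st)
        return st

    marked_substances = set(present)
    step(Phase.MARK_INITIAL, newly_marked_deletion=set(marked_substances))

    while marked_substances and len(g) > 0:
        # (a) delete marked substances; adjacent reactions become undefined
        marked_reactions = undefined_reactions(g, marked_substances)
        g.remove_nodes(marked_substances)
        step(
            Phase.DELETE_SUBSTANCES_MARK_REACTIONS,
            deleted=set(marked_substances),
            newly_marked_deletion=set(marked_reactions),
        )
        marked_substances = set()
        if not marked_reactions or len(g) == 0:
            break

        # (b) substances adjacent to the marked reactions go under inspection
        inspected: set[str] = set()
        for r in marked_reactions:
            inspected |= g.reactants(r)
            inspected |= g.products(r)
        step(Phase.MARK_INSPECTION, newly_marked_inspection=set(inspected))

        # (c) delete the reactions, then evaluate every inspected substance
        contexts = {
            s: InspectionContext(
                substance_id=s,
                lost_children=len(g.children(s) & marked_reactions),
                lost_parents=len(g.parents(s) & marked_reactions),
            )
            for s in inspected
        }
        g.remove_nodes(marked_reactions)
        kept: set[str] = set()
        for s in sorted(inspected):
            if inspect_substance(contexts[s], g) == "delete":
                marked_substances.add(s)
            else:
                kept.add(s)
        step(
            Phase.DELETE_REACTIONS_EVALUATE,
            deleted=set(marked_reactions),
            newly_marked_deletion=set(marked_substances),
            unmarked=kept,
        )

    result = PruneResult(graph=g, trace=trace, warnings=warnings)
    if result.is_empty:
        log.info("pruning emptied the graph: no viable synthesis route remains")
    return result
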