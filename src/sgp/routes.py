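"""Viable-route enumeration over synthesis graphs.

A synthesis graph is an AND/OR structure: a substance is an OR node (any
one producing reaction suffices) and a reaction is an AND node (all of its
reactants are required).  A *viable route* to the target is an acyclic
resolution of that structure whose leaves are starting materials: every
non-starting-material substance on the route is produced by exactly one
selected reaction, every selected reaction has all reactants on the route,
and no substance transitively requires itself.

Enumeration is exhaustive (up to ``max_routes``) and serves as the
independent correctness oracle for the pruning cascade: pruning away a set
of undesirable substances must leave exactly the union of the routes that
avoid them (:func:`union_of_routes`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import networkx as nx

from .graph_model import SynthesisGraph

DEFAULT_MAX_ROUTES = 10_000


class RouteError(ValueError):
    """Invalid input to route enumeration."""


@dataclass(frozen=True)
class SynthesisRoute:
    """An AND-tree of reactions resolving the target from starting materials.

    Routes are identified by their reaction set: the substance set follows
    from it (all reactants and products of the selected reactions plus the
    target), so two routes are distinct iff their reaction sets differ.
    """

    reactions: frozenset[str]
    substances: frozenset[str]
    target: str

    def sort_key(self) -> tuple[str, ...]:
        return tuple(sorted(self.reactions))

    def subgraph(self, graph: SynthesisGraph) -> SynthesisGraph:
        """The route as a synthesis graph (all edges of its reactions)."""
        return graph.subgraph_copy(self.reactions | self.substances)

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "reactions": sorted(self.reactions),
            "substances": sorted(self.substances),
        }


@dataclass
class RouteEnumeration(Sequence):
    """Result of :func:`enumerate_routes`: a list of routes plus a
    truncation flag set when ``max_routes`` was hit."""

    routes: list[SynthesisRoute] = field(default_factory=list)
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.routes)

    def __getitem__(self, i):
        return self.routes[i]

    def __iter__(self) -> Iterator[SynthesisRoute]:
        return iter(self.routes)

    def to_json(self) -> str:
        return json.dumps(
            {"truncated": self.truncated, "routes": [r.to_dict() for r in self.routes]},
            indent=2,
        )


# ---------------------------------------------------------------------------
# Route validity (independent of the enumeration path)
# ---------------------------------------------------------------------------


def route_violations(graph: SynthesisGraph, reactions: Iterable[str], target: str) -> list[str]:
    """Check a reaction set against the viable-route conditions.

    Returns a list of human-readable violations; empty means the reaction
    set constitutes a viable route to ``target``.  Used both as the test
    validator and as the brute-force subset oracle's membership predicate.
    Starting materials are leaves: a route never selects a producer for a
    non-target starting material, even if the graph contains one.
    """
    rxns = set(reactions)
    problems: list[str] = []
    if target not in graph or not graph.is_substance(target):
        return [f"target {target!r} is not a substance of the graph"]
    for r in rxns:
        if r not in graph or not graph.is_reaction(r):
            return [f"id {r!r} is not a reaction of the graph"]

    reactants: set[str] = set()
    products: set[str] = set()
    producer: dict[str, set[str]] = {}
    for r in rxns:
        reactants |= graph.reactants(r)
        for p in graph.products(r):
            products.add(p)
            producer.setdefault(p, set()).add(r)
    substances = reactants | products | {target}

    # the target needs a producer; on-route non-SM substances exactly one;
    # non-target starting materials are leaves and must have none.
    for s in substances:
        n_prod = len(producer.get(s, ()))
        is_sm = graph.is_starting_material(s)
        if s == target:
            if n_prod != 1:
                problems.append(f"target {s!r} has {n_prod} producing reactions on the route, expected 1")
        elif is_sm:
            if n_prod != 0:
                problems.append(f"starting material {s!r} is synthesized on the route")
        elif s in reactants:
            if n_prod != 1:
                problems.append(f"intermediate {s!r} has {n_prod} producing reactions on the route, expected 1")

    # no dangling branches: every non-target substance feeds some route reaction
    for s in substances - {target}:
        if s not in reactants:
            problems.append(f"substance {s!r} is produced but consumed by no route reaction")

    # acyclicity of the selected produce-dependency relation
    dep = nx.DiGraph()
    dep.add_nodes_from(substances)
    for p, rs in producer.items():
        for r in rs:
            for s in graph.reactants(r):
                dep.add_edge(p, s)  # p requires s
    if not nx.is_directed_acyclic_graph(dep):
        problems.append("a substance transitively requires itself")
    return problems


def is_viable_route(graph: SynthesisGraph, reactions: Iterable[str], target: str) -> bool:
    return not route_violations(graph, reactions, target)


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------


def enumerate_routes(
    graph: SynthesisGraph,
    target: Optional[str] = None,
    max_routes: int = DEFAULT_MAX_ROUTES,
) -> RouteEnumeration:
    """All distinct viable routes to ``target``, by AND/OR expansion.

    For the target one producing reaction is picked; each reactant that is
    not a starting material is resolved recursively by the same choice.  A
    substance already on the current dependency path may not be revisited,
    which makes the search terminate on cyclic graphs; completed selections
    whose dependency relation is cyclic across branches are discarded.
    Routes are returned in deterministic order (lexicographic by sorted
    reaction-id sequence).  ``target`` defaults to the graph's designated
    target.
    """
    if max_routes <= 0:
        raise RouteError(f"max_routes must be positive, got {max_routes}")
    if target is None:
        target = graph.target
    if target not in graph or not graph.is_substance(target):
        raise RouteError(f"target {target!r} is not a substance of the graph")

    found: dict[frozenset[str], SynthesisRoute] = {}
    truncated = False

    def resolve(pending: list[str], chosen: dict[str, str], ancestors: dict[str, frozenset[str]]) -> None:
        """Depth-first extension of a partial producer assignment.

        ``pending`` holds substances still awaiting a producer choice;
        ``ancestors[s]`` is a set of substances known to transitively
        require ``s``, used to cut off producer choices that would force a
        substance to participate in its own synthesis.  The cut-off is
        sound but not complete for cycles closed across AND-branches, so
        completed selections are re-checked by :func:`route_violations`.
        """
        nonlocal truncated
        if truncated:
            return
        while pending and (
            pending[-1] in chosen
            or (pending[-1] != target and graph.is_starting_material(pending[-1]))
        ):
            pending = pending[:-1]
        if not pending:
            rxns = frozenset(chosen.values())
            if rxns not in found and not route_violations(graph, rxns, target):
                substances = {target}
                for r in rxns:
                    substances |= graph.reactants(r) | graph.products(r)
                found[rxns] = SynthesisRoute(rxns, frozenset(substances), target)
                if len(found) >= max_routes:
                    truncated = True
            return
        s = pending[-1]
        rest = pending[:-1]
        blocked = ancestors.get(s, frozenset()) | {s}
        for r in sorted(graph.parents(s)):
            needs = sorted(graph.reactants(r))
            if any(n in blocked for n in needs):
                continue  # the reactant already requires s: certain cycle
            new_anc = dict(ancestors)
            for n in needs:
                if n not in chosen:
                    new_anc[n] = new_anc.get(n, frozenset()) | blocked
            resolve(rest + needs, {**chosen, s: r}, new_anc)

    resolve([target], {}, {})
    routes = sorted(found.values(), key=SynthesisRoute.sort_key)
    return RouteEnumeration(routes=routes, truncated=truncated)


def count_routes(graph: SynthesisGraph, target: Optional[str] = None, max_routes: int = DEFAULT_MAX_ROUTES) -> int:
    """Number of distinct viable routes to the target."""
    return len(enumerate_routes(graph, target, max_routes))


def routes_through(
    graph: SynthesisGraph,
    target: Optional[str] = None,
    via: str = "",
    max_routes: int = DEFAULT_MAX_ROUTES,
) -> int:
    """Number of viable routes whose substance set contains ``via``."""
    if not via:
        raise RouteError("routes_through requires a via substance id")
    return sum(1 for r in enumerate_routes(graph, target, max_routes) if via in r.substances)


def union_of_routes(
    graph: SynthesisGraph,
    target: Optional[str] = None,
    avoid: Iterable[str] = (),
    max_routes: int = DEFAULT_MAX_ROUTES,
) -> SynthesisGraph:
    """Union of all viable routes that touch no substance in ``avoid``.

    Discarding every route that intersects the avoid set and merging the
    survivors yields exactly the graph the pruning cascade should produce
    on route-covered inputs, which makes this the brute-force surrogate
    oracle for pruning correctness.  Returns an empty graph when no route
    survives.
    """
    avoid = set(avoid)
    nodes: set[str] = set()
    for route in enumerate_routes(graph, target, max_routes):
        if route.substances & avoid:
            continue
        nodes |= route.reactions | route.substances
    return graph.subgraph_copy(nodes)
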