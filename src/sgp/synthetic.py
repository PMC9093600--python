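"""Random synthesis-graph generation and the worked-example fixtures.

The generator emulates the kind of graph a retrosynthetic traversal of a
reaction knowledgebase produces: a layered AND/OR expansion below a single
target, with alternative producing reactions for some intermediates,
inventory-available leaves, and (optionally) directed cycles introduced by
back-edges.  Every generated graph is *route-covered* — each node lies on
at least one viable synthesis route — which is verified internally with
the route enumerator and is the precondition under which pruning is
equivalent to discarding-and-merging routes.

The fixture builders return the small didactic graphs of the worked
examples together with their documented undesirable sets.  The graphs are
frozen as edge-list CSV pairs shipped with the package; the documented
adjacency facts about them are asserted in the test suite so transcription
errors fail loudly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from . import graph_model
from .core import UndesirableSet
from .graph_model import SynthesisGraph, validate
from .routes import union_of_routes

MAX_GENERATION_ATTEMPTS = 80


class GenerationError(RuntimeError):
    """Raised when no route-covered graph could be drawn for a config."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the random synthesis-graph generator.

    ``n_layers`` is the depth of the expansion below the target;
    ``reactions_per_layer`` a lower bound on reactions created per layer
    (extras become alternative producers); ``reactants_per_reaction`` an
    inclusive (min, max) range; ``sm_fraction`` the probability that an
    *interior* substance is additionally flagged inventory-available
    (leaves are always starting materials, otherwise no route could ground
    out); ``alt_route_prob`` the per-substance chance of one extra
    producing reaction; ``cycle_prob`` the per-reaction chance of gaining a
    back-edge reactant from a higher layer, creating a directed cycle.
    """

    n_layers: int = 3
    reactions_per_layer: int = 2
    reactants_per_reaction: tuple[int, int] = (1, 3)
    sm_fraction: float = 0.2
    alt_route_prob: float = 0.3
    cycle_prob: float = 0.0
    seed: int = 0

    def check(self) -> None:
        if self.n_layers < 1:
            raise GenerationError("n_layers must be >= 1")
        if self.reactions_per_layer < 1:
            raise GenerationError("reactions_per_layer must be >= 1")
        lo, hi = self.reactants_per_reaction
        if not (1 <= lo <= hi):
            raise GenerationError(f"reactants_per_reaction range {self.reactants_per_reaction} is empty")
        for name in ("sm_fraction", "alt_route_prob", "cycle_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise GenerationError(f"{name}={p} is not a probability")


def generate(config: GeneratorConfig) -> SynthesisGraph:
    """Draw a validated, route-covered synthesis graph; reproducible per seed.

    Cyclic draws can strand nodes off every route, so the generator checks
    coverage after each draw and redraws (bounded attempts) before failing.
    The returned graph records whether any back-edge was added under the
    graph attribute ``has_back_edges``.
    """
    config.check()
    rng = random.Random(config.seed)
    last_problem = "no attempt made"
    for _ in range(MAX_GENERATION_ATTEMPTS):
        g = _draw(config, rng)
        report = validate(g)
        if not report.ok:
            last_problem = f"validation: {report.violations}"
            continue
        covered = set(union_of_routes(g, g.target).nx.nodes)
        if covered == set(g.nx.nodes):
            return g
        last_problem = f"nodes off every route: {sorted(set(g.nx.nodes) - covered)}"
    # An interior substance flagged inventory-available strands its
    # producing reactions off every route (routes treat starting materials
    # as leaves), so such draws are rejected by the coverage check; high
    # sm_fraction on deep graphs therefore costs retries.
    raise GenerationError(
        f"could not draw a route-covered graph for {config} "
        f"after {MAX_GENERATION_ATTEMPTS} attempts ({last_problem})"
    )


def _draw(config: GeneratorConfig, rng: random.Random) -> SynthesisGraph:
    g = SynthesisGraph()
    g.add_substance("T", is_target=True)
    lo, hi = config.reactants_per_reaction
    n_sub = 0
    n_rxn = 0
    layers: list[list[str]] = [["T"]]  # index 0 = target layer, grows downward

    def new_substance() -> str:
        nonlocal n_sub
        n_sub += 1
        sid = f"S{n_sub}"
        g.add_substance(sid)
        return sid

    def add_reaction(product: str, pool: list[str]) -> list[str]:
        """One producer of ``product`` drawing reactants from ``pool``
        (reusing existing pool members about a third of the time)."""
        nonlocal n_rxn
        n_rxn += 1
        rid = f"R{n_rxn}"
        g.add_reaction(rid)
        k = rng.randint(lo, hi)
        reactants: set[str] = set()
        while len(reactants) < k:
            if pool and rng.random() < 0.35:
                reactants.add(rng.choice(pool))
            else:
                s = new_substance()
                pool.append(s)
                reactants.add(s)
        for s in sorted(reactants):
            g.add_edge(s, rid)
        g.add_edge(rid, product)
        return pool

    for depth in range(config.n_layers):
        current = layers[depth]
        pool: list[str] = []
        produced_here: list[str] = []
        for s in current:
            # every substance that is not a forced leaf gets one producer
            add_reaction(s, pool)
            produced_here.append(s)
        extra = config.reactions_per_layer - len(current)
        for _ in range(max(0, extra)):
            add_reaction(rng.choice(produced_here), pool)
        for s in current:
            if rng.random() < config.alt_route_prob:
                add_reaction(s, pool)
        layers.append(pool)

    # leaves must be inventory-available; interior substances sometimes are
    for s in sorted(g.substances):
        if g.nx.in_degree(s) == 0:
            g.nx.nodes[s]["is_starting_material"] = True
        elif s != "T" and rng.random() < config.sm_fraction:
            g.nx.nodes[s]["is_starting_material"] = True

    # back-edges: a reaction gains an extra reactant that is reachable from
    # the reaction itself, which closes a directed cycle.  A back-edge into
    # a reaction that every surviving route needs would destroy route
    # coverage, so each candidate is kept only if coverage still holds.
    has_back_edges = False
    if config.cycle_prob > 0:
        import networkx as nx

        all_nodes = set(g.nx.nodes)
        for r in sorted(g.reactions):
            if rng.random() >= config.cycle_prob:
                continue
            downstream = [
                s
                for s in sorted(nx.descendants(g.nx, r))
                if g.is_substance(s) and s != "T" and not g.nx.has_edge(s, r)
            ]
            rng.shuffle(downstream)
            for s in downstream:
                g.add_edge(s, r)
                if set(union_of_routes(g, "T").nx.nodes) == all_nodes:
                    has_back_edges = True
                    break
                g.nx.remove_edge(s, r)
    g.nx.graph["has_back_edges"] = has_back_edges
    return g


# ---------------------------------------------------------------------------
# Worked-example fixtures
# ---------------------------------------------------------------------------

#: fixture name -> (edge-list CSV stem, undesirable substance ids)
_FIXTURES: dict[str, tuple[str, tuple[str, ...]]] = {
    "fig1": ("fig1", ("H", "I")),
    "case1": ("case1", ("U",)),
    "case2": ("case2", ("U11", "U12", "U21", "U22", "U31", "U32", "U41", "U42", "U51", "U52")),
    "case3": ("case2", ("U11", "U21", "U31", "U41", "U51", "C1")),
    "case4": ("case4", ("V",)),
    "case5": ("case2", ("M",)),
    "case6": ("case6", ("A",)),
    "case7": ("case7", ("A",)),
    "usecase_a": ("usecase_a", ("2",)),
    "usecase_b": ("usecase_b", ("6",)),
    # the individual use-case scenarios over the shared underlying graph
    "usecase1": ("usecase_a", ("2",)),
    "usecase2": ("usecase_a", ("3",)),
    "usecase3a": ("usecase_a", ("6",)),
    "usecase3b": ("usecase_b", ("6",)),
    "usecase4": ("usecase_a", ("2", "7", "8", "9", "10", "12")),
}


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def fixture(name: str) -> tuple[SynthesisGraph, UndesirableSet]:
    """A worked-example graph and its documented undesirable set.

    Available names: the step-by-step walkthrough graph (``fig1``), the
    seven didactic case graphs (``case1`` … ``case7``, where cases 2/3/5
    share one graph and case 4 differs only in inventory flags, and cases
    6/7 are the cyclic pair differing in one inventory flag), and the
    knowledgebase-extracted use-case graph (``usecase_a``/``usecase_b``,
    differing only in whether substance 5 is a starting material) plus the
    per-scenario aliases ``usecase1``, ``usecase2``, ``usecase3a``,
    ``usecase3b`` and ``usecase4``.
    """
    try:
        stem, undesirable = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        ) from None
    base = resources.files("sgp") / "fixtures"
    with resources.as_file(base / f"{stem}.nodes.csv") as p:
        graph = graph_model.read_graph(str(p)[: -len(".nodes.csv")], fmt="edgelist")
    return graph, UndesirableSet(undesirable)
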