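"""Shared helpers: node-order shuffling and random sweep configurations."""

from __future__ import annotations

import random

import pytest

from sgp import GeneratorConfig, SynthesisGraph, generate

#: every shipped worked-example fixture, including per-scenario aliases
ALL_FIXTURES = [
    "fig1",
    "case1",
    "case2",
    "case3",
    "case4",
    "case5",
    "case6",
    "case7",
    "usecase1",
    "usecase2",
    "usecase3a",
    "usecase3b",
    "usecase4",
]


def shuffled(graph: SynthesisGraph, seed: int) -> SynthesisGraph:
    """Rebuild ``graph`` with node and edge insertion order permuted.

    networkx iterates nodes in insertion order, so this exercises any
    hidden dependence of the cascade on iteration order.
    """
    rng = random.Random(seed)
    nodes = list(graph.nx.nodes)
    edges = list(graph.nx.edges)
    rng.shuffle(nodes)
    rng.shuffle(edges)
    out = SynthesisGraph()
    for n in nodes:
        d = graph.nx.nodes[n]
        if d["node_type"] == "substance":
            out.add_substance(
                n,
                label=d.get("label"),
                is_starting_material=bool(d.get("is_starting_material")),
                is_target=bool(d.get("is_target")),
                mw=d.get("mw"),
            )
        else:
            out.add_reaction(n, label=d.get("label"))
    for u, v in edges:
        out.add_edge(u, v)
    return out


def sweep_config(rng: random.Random, seed: int, cycle_prob: float) -> GeneratorConfig:
    """A small random generator configuration for property sweeps."""
    n_layers = rng.choice([2, 3])
    return GeneratorConfig(
        n_layers=n_layers,
        reactions_per_layer=rng.choice([1, 2]),
        reactants_per_reaction=(1, rng.choice([2, 3]) if n_layers == 2 else 2),
        sm_fraction=0.15,
        alt_route_prob=rng.choice([0.2, 0.4]),
        cycle_prob=cycle_prob,
        seed=seed,
    )


def draw_small(rng: random.Random, seed: int, cycle_prob: float, max_substances: int = 30) -> SynthesisGraph:
    """Draw a route-covered graph with at most ``max_substances`` substances."""
    for attempt in range(20):
        g = generate(sweep_config(rng, seed + 10_000 * attempt, cycle_prob))
        if len(g.substances) <= max_substances:
            return g
    pytest.fail(f"could not draw a graph with <= {max_substances} substances")
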