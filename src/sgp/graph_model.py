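"""Data model and file I/O for bipartite synthesis graphs.

A synthesis graph is a directed, not necessarily acyclic, bipartite graph
with two node kinds: *substances* (molecules) and *reactions*.  An edge
``substance -> reaction`` records a reactant/reagent role; an edge
``reaction -> substance`` records a product role.  Substance nodes carry
inventory metadata: ``is_starting_material`` marks a substance as readily
available from the inventory, ``is_target`` designates the molecule whose
synthesis the graph encodes, and ``mw`` optionally records molecular weight
in g/mol (used only by inventory inference).

The model is a thin, validated wrapper over :class:`networkx.DiGraph`, so
all generic graph algorithms remain available through the ``nx`` attribute.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import networkx as nx
from lxml import etree

log = logging.getLogger(__name__)

SUBSTANCE = "substance"
REACTION = "reaction"

#: Node attributes with a fixed meaning; everything else read from a file is
#: preserved as an opaque annotation and re-emitted on write (GraphML only).
RESERVED_ATTRS = ("node_type", "label", "is_starting_material", "is_target", "mw")


class GraphModelError(ValueError):
    """Base error for graph construction and I/O problems."""


class ParseError(GraphModelError):
    """Raised when an input file cannot be parsed in the named format."""


class LoadError(GraphModelError):
    """Raised when a parsed file yields a graph that fails validation."""

    def __init__(self, message: str, report: "ValidationReport"):
        super().__init__(message)
        self.report = report


@dataclass(frozen=True)
class Violation:
    code: str
    ref: str  # node id or "source->target" for edges
    message: str


@dataclass
class ValidationReport:
    """Outcome of :func:`validate`: hard violations plus advisory warnings.

    ``ok`` is true iff there are no violations; warnings (e.g. a reaction
    currently lacking a reactant, which legitimately happens in pruned
    intermediate states) never make a graph invalid.
    """

    violations: list[Violation] = field(default_factory=list)
    warnings: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


class SynthesisGraph:
    """Directed bipartite graph of substance and reaction nodes."""

    def __init__(self) -> None:
        self.nx = nx.DiGraph()

    # -- construction -------------------------------------------------

    def add_substance(
        self,
        node_id: str,
        label: Optional[str] = None,
        is_starting_material: bool = False,
        is_target: bool = False,
        mw: Optional[float] = None,
        **extra: object,
    ) -> None:
        if node_id in self.nx:
            raise GraphModelError(f"duplicate node id {node_id!r}")
        self.nx.add_node(
            node_id,
            node_type=SUBSTANCE,
            label=label if label is not None else node_id,
            is_starting_material=bool(is_starting_material),
            is_target=bool(is_target),
            **({"mw": float(mw)} if mw is not None else {}),
            **extra,
        )

    def add_reaction(self, node_id: str, label: Optional[str] = None, **extra: object) -> None:
        if node_id in self.nx:
            raise GraphModelError(f"duplicate node id {node_id!r}")
        self.nx.add_node(node_id, node_type=REACTION, label=label if label is not None else node_id, **extra)

    def add_edge(self, source: str, target: str) -> None:
        for n in (source, target):
            if n not in self.nx:
                raise GraphModelError(f"edge endpoint {n!r} is not a node of the graph")
        if self.nx.has_edge(source, target):
            log.warning("duplicate edge %s->%s collapsed (set semantics)", source, target)
            return
        self.nx.add_edge(source, target)

    # -- node sets -----------------------------------------------------

    def node_kind(self, node_id: str) -> str:
        return self.nx.nodes[node_id]["node_type"]

    def is_substance(self, node_id: str) -> bool:
        return node_id in self.nx and self.node_kind(node_id) == SUBSTANCE

    def is_reaction(self, node_id: str) -> bool:
        return node_id in self.nx and self.node_kind(node_id) == REACTION

    @property
    def substances(self) -> set[str]:
        return {n for n, d in self.nx.nodes(data=True) if d["node_type"] == SUBSTANCE}

    @property
    def reactions(self) -> set[str]:
        return {n for n, d in self.nx.nodes(data=True) if d["node_type"] == REACTION}

    @property
    def targets(self) -> set[str]:
        return {n for n in self.substances if self.nx.nodes[n].get("is_target")}

    @property
    def target(self) -> str:
        """The designated target molecule; error unless exactly one exists."""
        t = self.targets
        if len(t) != 1:
            raise GraphModelError(f"graph has {len(t)} designated targets, expected exactly 1")
        return next(iter(t))

    def is_starting_material(self, substance_id: str) -> bool:
        return bool(self.nx.nodes[substance_id].get("is_starting_material"))

    def is_target_node(self, substance_id: str) -> bool:
        return bool(self.nx.nodes[substance_id].get("is_target"))

    # -- neighbourhoods ------------------------------------------------
    # "child" of a substance = reaction consuming it; "parent" = reaction
    # producing it.  For reactions the field terms are reactants/products.

    def children(self, substance_id: str) -> set[str]:
        return set(self.nx.successors(substance_id))

    def parents(self, substance_id: str) -> set[str]:
        return set(self.nx.predecessors(substance_id))

    def reactants(self, reaction_id: str) -> set[str]:
        return set(self.nx.predecessors(reaction_id))

    def products(self, reaction_id: str) -> set[str]:
        return set(self.nx.successors(reaction_id))

    # -- utilities -----------------------------------------------------

    def copy(self) -> "SynthesisGraph":
        g = SynthesisGraph()
        g.nx = self.nx.copy()
        return g

    def remove_nodes(self, node_ids: Iterable[str]) -> None:
        self.nx.remove_nodes_from(list(node_ids))

    def subgraph_copy(self, node_ids: Iterable[str]) -> "SynthesisGraph":
        g = SynthesisGraph()
        g.nx = self.nx.subgraph(list(node_ids)).copy()
        return g

    def __len__(self) -> int:
        return len(self.nx)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nx

    def __iter__(self) -> Iterator[str]:
        return iter(self.nx)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SynthesisGraph):
            return NotImplemented
        if set(self.nx.nodes) != set(other.nx.nodes):
            return False
        if set(self.nx.edges) != set(other.nx.edges):
            return False
        for n in self.nx.nodes:
            a, b = self.nx.nodes[n], other.nx.nodes[n]
            if a["node_type"] != b["node_type"]:
                return False
            if a["node_type"] == SUBSTANCE:
                for key in ("is_starting_material", "is_target"):
                    if bool(a.get(key)) != bool(b.get(key)):
                        return False
                if a.get("mw") != b.get("mw"):
                    return False
        return True

    def __hash__(self):  # mutable container
        raise TypeError("SynthesisGraph is unhashable")

    def __repr__(self) -> str:
        return (
            f"<SynthesisGraph |S|={len(self.substances)} |R|={len(self.reactions)} "
            f"|E|={self.nx.number_of_edges()}>"
        )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate(graph: SynthesisGraph) -> ValidationReport:
    """Check the bipartite invariants; violations are data, not exceptions.

    Hard violations: an edge joining two nodes of the same kind
    (``BIPARTITE``, covers self-loops), a negative molecular weight
    (``NEGATIVE_MW``) and more than one designated target (``MULTI_TARGET``).
    Warnings: a reaction with no reactant or no product, and a graph with
    no designated target — both are legal intermediate states.
    """
    report = ValidationReport()
    g = graph.nx
    for u, v in g.edges:
        if g.nodes[u]["node_type"] == g.nodes[v]["node_type"]:
            report.violations.append(
                Violation("BIPARTITE", f"{u}->{v}", f"edge joins two {g.nodes[u]['node_type']} nodes")
            )
    for n in graph.substances:
        mw = g.nodes[n].get("mw")
        if mw is not None and mw < 0:
            report.violations.append(Violation("NEGATIVE_MW", n, f"molecular weight {mw} is negative"))
    targets = graph.targets
    if len(targets) > 1:
        report.violations.append(
            Violation("MULTI_TARGET", ",".join(sorted(targets)), "more than one designated target")
        )
    elif len(graph) > 0 and not targets:
        report.warnings.append(Violation("NO_TARGET", "", "no designated target molecule"))
    for r in graph.reactions:
        if g.in_degree(r) == 0:
            report.warnings.append(Violation("REACTION_NO_REACTANT", r, "reaction has no reactant"))
        if g.out_degree(r) == 0:
            report.warnings.append(Violation("REACTION_NO_PRODUCT", r, "reaction has no product"))
    return report


# ---------------------------------------------------------------------------
# Inventory inference
# ---------------------------------------------------------------------------


def infer_starting_materials(
    graph: SynthesisGraph,
    mw_threshold: float = 200.0,
    use_indegree_rule: bool = True,
    use_mw_rule: bool = True,
) -> SynthesisGraph:
    """Flag inventory-available substances on a copy of ``graph``.

    Two heuristics stand in for real inventory data: a substance with
    in-degree zero (nothing in the graph produces it) must come from the
    inventory, and a substance lighter than ``mw_threshold`` g/mol (strict
    inequality, default 200) is assumed to be a purchasable building block.
    Substances without an ``mw`` annotation are skipped by the weight rule.
    Existing flags are never cleared, so the operation is monotone and
    idempotent.
    """
    if mw_threshold < 0:
        raise GraphModelError(f"mw_threshold must be non-negative, got {mw_threshold}")
    out = graph.copy()
    for s in out.substances:
        data = out.nx.nodes[s]
        if use_indegree_rule and out.nx.in_degree(s) == 0:
            data["is_starting_material"] = True
        mw = data.get("mw")
        if use_mw_rule and mw is not None and mw < mw_threshold:
            data["is_starting_material"] = True
    return out


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_BOOL_TRUE = {"true", "1", "yes", "t"}
_BOOL_FALSE = {"false", "0", "no", "f", ""}


def _parse_bool(value: object, where: str) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _BOOL_TRUE:
        return True
    if s in _BOOL_FALSE:
        return False
    raise ParseError(f"{where}: cannot interpret {value!r} as a boolean")


def _finalize(graph: SynthesisGraph, origin: str) -> SynthesisGraph:
    report = validate(graph)
    if not report.ok:
        raise LoadError(
            f"{origin}: graph fails validation: "
            + "; ".join(f"{v.code}[{v.ref}] {v.message}" for v in report.violations),
            report,
        )
    return graph


def read_graph(path: str, fmt: Optional[str] = None) -> SynthesisGraph:
    """Read a synthesis graph from GraphML, XGMML or the edge-list dialect.

    ``fmt`` is one of ``graphml``, ``xgmml``, ``edgelist``; when omitted it
    is inferred from the file extension (``.csv`` and directories mean the
    edge-list dialect).  The loaded graph must pass :func:`validate`.
    """
    fmt = fmt or _infer_format(path)
    if fmt == "graphml":
        return _read_graphml(path)
    if fmt == "xgmml":
        return _read_xgmml(path)
    if fmt == "edgelist":
        return _read_edgelist(path)
    raise GraphModelError(f"unknown graph format {fmt!r}")


def write_graph(graph: SynthesisGraph, path: str, fmt: Optional[str] = None) -> None:
    """Write a graph in GraphML or the edge-list dialect (XGMML is read-only)."""
    fmt = fmt or _infer_format(path)
    if fmt == "graphml":
        _write_graphml(graph, path)
    elif fmt == "edgelist":
        _write_edgelist(graph, path)
    elif fmt == "xgmml":
        raise GraphModelError("XGMML is supported read-only")
    else:
        raise GraphModelError(f"unknown graph format {fmt!r}")


def _infer_format(path: str) -> str:
    if os.path.isdir(path):
        return "edgelist"
    ext = os.path.splitext(path)[1].lower()
    if ext == ".graphml":
        return "graphml"
    if ext == ".xgmml":
        return "xgmml"
    if ext == ".csv":
        return "edgelist"
    raise GraphModelError(f"cannot infer graph format from {path!r}; pass fmt explicitly")


# -- GraphML ----------------------------------------------------------------


def _read_graphml(path: str) -> SynthesisGraph:
    try:
        raw = nx.read_graphml(path)
    except Exception as exc:  # networkx wraps lxml/expat errors
        raise ParseError(f"{path}: not parseable as GraphML: {exc}") from exc
    g = SynthesisGraph()
    for n, data in raw.nodes(data=True):
        kind = data.get("node_type")
        if kind not in (SUBSTANCE, REACTION):
            raise ParseError(f"{path}: node {n!r} lacks a node_type of 'substance' or 'reaction'")
        extra = {k: v for k, v in data.items() if k not in RESERVED_ATTRS}
        if kind == SUBSTANCE:
            g.add_substance(
                str(n),
                label=data.get("label"),
                is_starting_material=_parse_bool(data.get("is_starting_material", False), f"node {n}"),
                is_target=_parse_bool(data.get("is_target", False), f"node {n}"),
                mw=data.get("mw"),
                **extra,
            )
        else:
            g.add_reaction(str(n), label=data.get("label"), **extra)
    for u, v in raw.edges:
        g.add_edge(str(u), str(v))
    return _finalize(g, path)


def _write_graphml(graph: SynthesisGraph, path: str) -> None:
    out = nx.DiGraph()
    for n in sorted(graph.nx.nodes):
        data = dict(graph.nx.nodes[n])
        if data["node_type"] == SUBSTANCE:
            data.setdefault("is_starting_material", False)
            data.setdefault("is_target", False)
        out.add_node(n, **{k: v for k, v in data.items() if v is not None})
    out.add_edges_from(sorted(graph.nx.edges))
    nx.write_graphml(out, path)


# -- XGMML (read-only subset) -----------------------------------------------


def _read_xgmml(path: str) -> SynthesisGraph:
    try:
        tree = etree.parse(path)
    except (OSError, etree.XMLSyntaxError) as exc:
        raise ParseError(f"{path}: not parseable as XGMML: {exc}") from exc
    root = tree.getroot()
    if etree.QName(root).localname != "graph":
        raise ParseError(f"{path}: root element is <{root.tag}>, expected <graph>")
    g = SynthesisGraph()
    edges: list[tuple[str, str, int]] = []
    for el in root:
        if not isinstance(el.tag, str):
            continue
        name = etree.QName(el).localname
        if name == "node":
            node_id = el.get("id")
            if node_id is None:
                raise ParseError(f"{path}: line {el.sourceline}: <node> without an id")
            atts = {
                a.get("name"): a.get("value")
                for a in el.iter()
                if isinstance(a.tag, str) and etree.QName(a).localname == "att"
            }
            kind = atts.get("node_type")
            if kind not in (SUBSTANCE, REACTION):
                raise ParseError(
                    f"{path}: line {el.sourceline}: node {node_id!r} lacks a "
                    "node_type att of 'substance' or 'reaction'"
                )
            if kind == SUBSTANCE:
                mw = atts.get("mw")
                g.add_substance(
                    node_id,
                    label=el.get("label"),
                    is_starting_material=_parse_bool(atts.get("is_starting_material", False), f"node {node_id}"),
                    is_target=_parse_bool(atts.get("is_target", False), f"node {node_id}"),
                    mw=float(mw) if mw not in (None, "") else None,
                )
            else:
                g.add_reaction(node_id, label=el.get("label"))
        elif name == "edge":
            src, tgt = el.get("source"), el.get("target")
            if src is None or tgt is None:
                raise ParseError(f"{path}: line {el.sourceline}: <edge> without source/target")
            edges.append((src, tgt, el.sourceline))
    for src, tgt, line in edges:
        try:
            g.add_edge(src, tgt)
        except GraphModelError as exc:
            raise ParseError(f"{path}: line {line}: {exc}") from exc
    return _finalize(g, path)


# -- edge-list dialect ------------------------------------------------------
# Two UTF-8 CSV files with header rows:
#   nodes.csv: id,node_type,label,is_starting_material,is_target,mw
#   edges.csv: source,target
# ``path`` may be a directory (containing nodes.csv/edges.csv) or a prefix:
# "foo.csv" and "foo" both mean foo.nodes.csv + foo.edges.csv.

NODE_FIELDS = ["id", "node_type", "label", "is_starting_material", "is_target", "mw"]
EDGE_FIELDS = ["source", "target"]


def edgelist_paths(path: str) -> tuple[str, str]:
    if os.path.isdir(path):
        return os.path.join(path, "nodes.csv"), os.path.join(path, "edges.csv")
    stem = path[: -len(".csv")] if path.lower().endswith(".csv") else path
    if stem.endswith((".nodes", ".edges")):
        stem = stem[: -len(".nodes")]
    return f"{stem}.nodes.csv", f"{stem}.edges.csv"


def _read_edgelist(path: str) -> SynthesisGraph:
    nodes_path, edges_path = edgelist_paths(path)
    g = SynthesisGraph()
    try:
        with open(nodes_path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "id" not in reader.fieldnames or "node_type" not in reader.fieldnames:
                raise ParseError(f"{nodes_path}: header row with at least id,node_type required")
            for i, row in enumerate(reader, start=2):
                where = f"{nodes_path}:{i}"
                node_id, kind = row["id"], row["node_type"]
                if kind == SUBSTANCE:
                    mw = row.get("mw") or None
                    g.add_substance(
                        node_id,
                        label=row.get("label") or None,
                        is_starting_material=_parse_bool(row.get("is_starting_material", ""), where),
                        is_target=_parse_bool(row.get("is_target", ""), where),
                        mw=float(mw) if mw is not None else None,
                    )
                elif kind == REACTION:
                    g.add_reaction(node_id, label=row.get("label") or None)
                else:
                    raise ParseError(f"{where}: unknown node_type {kind!r}")
        with open(edges_path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or set(EDGE_FIELDS) - set(reader.fieldnames):
                raise ParseError(f"{edges_path}: header row source,target required")
            for i, row in enumerate(reader, start=2):
                try:
                    g.add_edge(row["source"], row["target"])
                except GraphModelError as exc:
                    raise ParseError(f"{edges_path}:{i}: {exc}") from exc
    except FileNotFoundError as exc:
        raise ParseError(f"{exc.filename}: file not found") from exc
    return _finalize(g, path)


def _write_edgelist(graph: SynthesisGraph, path: str) -> None:
    nodes_path, edges_path = edgelist_paths(path)
    if os.path.isdir(path):
        pass
    else:
        parent = os.path.dirname(nodes_path)
        if parent:
            os.makedirs(parent, exist_ok=True)
    with open(nodes_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(NODE_FIELDS)
        for n in sorted(graph.nx.nodes):
            d = graph.nx.nodes[n]
            if d["node_type"] == SUBSTANCE:
                writer.writerow(
                    [
                        n,
                        SUBSTANCE,
                        d.get("label", n),
                        str(bool(d.get("is_starting_material"))).lower(),
                        str(bool(d.get("is_target"))).lower(),
                        d.get("mw", ""),
                    ]
                )
            else:
                writer.writerow([n, REACTION, d.get("label", n), "", "", ""])
    with open(edges_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EDGE_FIELDS)
        for u, v in sorted(graph.nx.edges):
            writer.writerow([u, v])
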