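"""Vertical integration of the three network layers.

The conceptual (ontology-anchored) layer acts as the hub: its nodes are
compared pairwise against gene-layer and clinical-layer nodes, and a
semantic link is recorded whenever the two nodes resolve to the same
concept, to concepts joined by a direct is-a edge (parent-child), or to
concepts sharing an is-a parent (sibling).  Breadth-first search over the
union of within-layer edges and cross-links then extracts simple paths
from one layer to another — "vertical complexes" of biomarkers and
phenotypes spanning levels of granularity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .synthio import Ontology

logger = logging.getLogger(__name__)

__all__ = [
    "LayerNetwork",
    "MultiNetwork",
    "VerticalComplex",
    "semantic_link",
    "cross_link",
    "extract_complexes",
]

LAYERS = ("gene", "conceptual", "clinical")


@dataclass
class LayerNetwork:
    """One layer: a labeled graph plus an optional node -> concept id map."""

    layer: str  # "gene" | "conceptual" | "clinical"
    graph: nx.Graph
    concept_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")

    def concept(self, node: str) -> str:
        """Concept id a node resolves to (defaults to its own label)."""
        return self.concept_of.get(node, node)


@dataclass(frozen=True)
class CrossLink:
    node_a: str
    layer_a: str
    node_b: str
    layer_b: str
    link_type: str  # "identical" | "parent_child" | "sibling"


@dataclass
class MultiNetwork:
    layers: dict[str, LayerNetwork]
    cross_links: set[CrossLink] = field(default_factory=set)
    annotations: dict[CrossLink, str] = field(default_factory=dict)

    def union_graph(self) -> nx.Graph:
        """Layer-tagged union of within-layer edges and cross-links; nodes
        are (layer, node) pairs, edges carry ``provenance``."""
        g = nx.Graph()
        for name, layer in self.layers.items():
            for n in layer.graph.nodes:
                g.add_node((name, n))
            for u, v in layer.graph.edges:
                g.add_edge((name, u), (name, v), provenance="within", layer=name)
        for cl in self.cross_links:
            g.add_edge(
                (cl.layer_a, cl.node_a),
                (cl.layer_b, cl.node_b),
                provenance="cross",
                link_type=cl.link_type,
            )
        return g


@dataclass
class VerticalComplex:
    """A simple path across the multi-network with per-hop provenance."""

    nodes: list[tuple[str, str]]  # (layer, node)
    hops: list[str]  # provenance per hop: "within:<layer>" or "cross:<type>"

    @property
    def layers_spanned(self) -> set[str]:
        return {layer for layer, _ in self.nodes}

    @property
    def initial(self) -> tuple[str, str]:
        return self.nodes[0]

    @property
    def terminal(self) -> tuple[str, str]:
        return self.nodes[-1]

    def __len__(self) -> int:
        return len(self.hops)


def _isa_parents(onto: Ontology) -> dict[str, set[str]]:
    parents: dict[str, set[str]] = {c: set() for c in onto.concepts}
    for s, lbl, t in onto.relations:
        if lbl in onto.isa_labels:
            parents[s].add(t)
    return parents


def _resolve(label: str, onto: Ontology) -> str | None:
    """Resolve a node label to a concept id: exact id, else exact
    case-insensitive name/synonym match."""
    if label in onto.concepts:
        return label
    low = label.lower()
    hits = [
        cid
        for cid, meta in onto.concepts.items()
        if meta["name"].lower() == low
        or any(s.lower() == low for s in meta.get("synonyms", ()))
    ]
    return sorted(hits)[0] if hits else None


def semantic_link(a: str, b: str, onto: Ontology) -> str | None:
    """identical > parent_child > sibling, or None.

    ``a`` and ``b`` are concept ids or labels resolvable to concepts.
    parent_child requires a direct is-a edge in either direction; sibling
    requires at least one shared is-a parent.
    """
    ca, cb = _resolve(a, onto), _resolve(b, onto)
    if ca is None or cb is None:
        logger.debug("unresolvable label in semantic_link: %r / %r", a, b)
        return None
    if ca == cb:
        return "identical"
    parents = _isa_parents(onto)
    if cb in parents[ca] or ca in parents[cb]:
        return "parent_child"
    if parents[ca] & parents[cb]:
        return "sibling"
    return None


def cross_link(
    layers: dict[str, LayerNetwork],
    onto: Ontology,
    pairings: tuple[tuple[str, str], ...] = (("conceptual", "gene"), ("conceptual", "clinical")),
) -> MultiNetwork:
    """Evaluate semantic links for every node pair across the given layer
    pairings (conceptual layer as the hub by default) and assemble the
    multi-network.  The result is independent of node enumeration order."""
    mn = MultiNetwork(layers=dict(layers))
    for la, lb in pairings:
        if la == lb:
            raise ValueError("cross-links join different layers only")
        A, B = layers[la], layers[lb]
        for na in sorted(A.graph.nodes):
            ca = A.concept_of.get(na, na)
            for nb in sorted(B.graph.nodes):
                cb = B.concept_of.get(nb, nb)
                lt = semantic_link(ca, cb, onto)
                if lt is not None:
                    mn.cross_links.add(CrossLink(na, la, nb, lb, lt))
    return mn


def extract_complexes(
    mn: MultiNetwork,
    start_layer: str,
    end_layer: str,
    max_len: int = 12,
    max_paths: int | None = None,
) -> list[VerticalComplex]:
    """All simple paths from start-layer nodes to end-layer nodes over the
    union of within-layer edges and cross-links, at most ``max_len`` hops.

    Results are sorted by (number of layers spanned descending, path length
    ascending, lexicographic node sequence).  An empty list means no path,
    which is not an error.  ``max_paths`` bounds the enumeration (in
    deterministic search order) for networks whose dense regions make the
    exhaustive path set combinatorially large; leave it None on small
    fixtures where the full set is wanted.
    """
    if not mn.cross_links:
        raise ValueError("multi-network has no cross-links")
    g = mn.union_graph()
    starts = sorted(n for n in g.nodes if n[0] == start_layer)
    ends = {n for n in g.nodes if n[0] == end_layer}
    out: list[VerticalComplex] = []
    seen: set[tuple] = set()
    budget = float("inf") if max_paths is None else max_paths
    for s in starts:
        if len(out) >= budget:
            break
        for path in nx.all_simple_paths(g, s, sorted(ends), cutoff=max_len):
            if len(out) >= budget:
                break
            key = min(tuple(path), tuple(reversed(path)))
            if key in seen:
                continue
            seen.add(key)
            if len({layer for layer, _ in path}) < 2:
                continue
            hops = []
            for u, v in zip(path, path[1:]):
                data = g.edges[u, v]
                if data["provenance"] == "within":
                    hops.append(f"within:{data['layer']}")
                else:
                    hops.append(f"cross:{data['link_type']}")
            out.append(VerticalComplex(nodes=list(path), hops=hops))
    out.sort(key=lambda c: (-len(c.layers_spanned), len(c), c.nodes))
    return out
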