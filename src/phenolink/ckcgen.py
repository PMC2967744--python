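"""Knowledge-anchored concept network via constructive induction.

Data-dictionary elements are lexically mapped to ontology concepts
(token-set Jaccard over normalized names and synonyms).  Conceptual
knowledge constructs (CKCs) are then enumerated: simple relation paths
between concepts mapped from *different* elements, routed through one or
more intermediate concepts not required to be mapped themselves.  A
granularity filter keeps only chains whose intermediates sit within a
bounded is-a-depth distance of both endpoints, so chains do not jump
between wildly different levels of abstraction.  Valid chains are finally
aggregated into a concept-layer network.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import networkx as nx

from .synthio import Ontology

__all__ = [
    "ElementMapping",
    "CKC",
    "map_elements",
    "concept_depths",
    "generate_ckcs",
    "ckc_network",
    "tokenize",
]


@dataclass
class ElementMapping:
    element: str
    element_kind: str  # "phenotypic" | "bio-molecular"
    concepts: dict[str, float]  # concept id -> match score in [0, 1]

    @property
    def mapped(self) -> bool:
        return bool(self.concepts)

    def best(self) -> str | None:
        if not self.concepts:
            return None
        return max(self.concepts, key=lambda c: (self.concepts[c], c))


@dataclass(frozen=True)
class CKC:
    """Alternating concept/relation chain; endpoints are mapped concepts."""

    concepts: tuple[str, ...]
    relations: tuple[str, ...]
    annotation: tuple[str, str] | None = None  # (validity, meaningfulness)

    def __post_init__(self) -> None:
        if len(self.concepts) < 3:
            raise ValueError("a CKC needs at least 3 concepts")
        if len(self.relations) != len(self.concepts) - 1:
            raise ValueError("need exactly one relation per consecutive pair")
        if len(set(self.concepts)) != len(self.concepts):
            raise ValueError("CKC chain must be a simple path")

    @property
    def endpoints(self) -> tuple[str, str]:
        return self.concepts[0], self.concepts[-1]

    @property
    def intermediates(self) -> tuple[str, ...]:
        return self.concepts[1:-1]

    def serialize(self) -> str:
        parts = [self.concepts[0]]
        for rel, c in zip(self.relations, self.concepts[1:]):
            parts += [rel, c]
        return "|".join(parts)

    def canonical(self) -> tuple:
        """Orientation-free key used to deduplicate reversed chains."""
        fwd = (self.concepts, self.relations)
        rev = (self.concepts[::-1], self.relations[::-1])
        return min(fwd, rev)


_PUNCT = re.compile(r"[^\w\s]")


def tokenize(text: str) -> frozenset[str]:
    """Case-folded, punctuation-stripped token set."""
    return frozenset(_PUNCT.sub(" ", text.lower()).split())


def map_elements(
    dictionary: list[tuple[str, str]] | list[str],
    onto: Ontology,
    min_score: float = 0.2,
) -> list[ElementMapping]:
    """Lexically map data-dictionary elements to ontology concepts.

    ``dictionary`` entries are (element, kind) pairs or bare element names
    (kind defaults to phenotypic).  Score is the token-set Jaccard between
    the element name and the concept's preferred name or best synonym;
    matches at or above ``min_score`` are kept, best-first.  Elements with
    no match are retained with an empty concept set.
    """
    if not dictionary:
        raise ValueError("dictionary must be non-empty")
    entries = [
        (e, "phenotypic") if isinstance(e, str) else (e[0], e[1]) for e in dictionary
    ]
    concept_tokens = {
        cid: [tokenize(meta["name"])] + [tokenize(s) for s in meta.get("synonyms", [])]
        for cid, meta in onto.concepts.items()
    }
    out = []
    for element, kind in entries:
        etoks = tokenize(element)
        scores: dict[str, float] = {}
        for cid, variants in concept_tokens.items():
            best = 0.0
            for v in variants:
                union = etoks | v
                if union:
                    best = max(best, len(etoks & v) / len(union))
            if best >= min_score:
                scores[cid] = best
        out.append(ElementMapping(element=element, element_kind=kind, concepts=scores))
    return out


def concept_depths(onto: Ontology) -> dict[str, int]:
    """Shortest is-a path length from any root (in-degree-0 concept of the
    child->parent hierarchy, i.e. a concept with no parent)."""
    g = onto.isa_graph()  # child -> parent
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("is-a subgraph has a cycle")
    down = g.reverse()  # parent -> child
    roots = [c for c in down.nodes if g.out_degree(c) == 0]
    depths: dict[str, int] = {}
    for r in roots:
        for node, d in nx.single_source_shortest_path_length(down, r).items():
            if node not in depths or d < depths[node]:
                depths[node] = d
    return depths


def _traversal_graph(onto: Ontology) -> nx.Graph:
    """Undirected multigraph-flattened traversal view: associative relations
    are direction-agnostic and is-a may be walked either way; parallel
    relations collapse to one edge carrying all labels."""
    g = nx.Graph()
    g.add_nodes_from(onto.concepts)
    for s, lbl, t in sorted(onto.relations):
        if g.has_edge(s, t):
            g.edges[s, t]["labels"] = tuple(sorted(set(g.edges[s, t]["labels"]) | {lbl}))
        else:
            g.add_edge(s, t, labels=(lbl,))
    return g


def generate_ckcs(
    mappings: list[ElementMapping],
    onto: Ontology,
    max_intermediates: int = 1,
    granularity_delta: int = 1,
) -> list[CKC]:
    """Enumerate CKCs between concepts mapped from different elements.

    For every unordered pair of mapped concepts originating from different
    elements, all simple relation paths with 1..max_intermediates interior
    concepts are enumerated over the traversal view of the ontology; a path
    survives only if every interior concept c satisfies
    |depth(c) - depth(endpoint)| <= granularity_delta for both endpoints.
    Reversed duplicates are removed.  When an edge carries several relation
    labels, the lexicographically smallest is reported.
    """
    mapped = [m for m in mappings if m.mapped]
    if len(mapped) < 2:
        raise ValueError("need at least 2 mapped elements")
    concept_elements: dict[str, set[str]] = {}
    for m in mapped:
        for cid in m.concepts:
            concept_elements.setdefault(cid, set()).add(m.element)

    depths = concept_depths(onto)
    trav = _traversal_graph(onto)
    seen: set[tuple] = set()
    out: list[CKC] = []
    concept_ids = sorted(concept_elements)
    for i, a in enumerate(concept_ids):
        for b in concept_ids[i + 1 :]:
            if concept_elements[a] == concept_elements[b] and len(concept_elements[a]) == 1:
                continue  # same single element on both ends
            if a not in trav or b not in trav:
                continue
            for path in nx.all_simple_paths(trav, a, b, cutoff=max_intermediates + 1):
                if len(path) < 3:
                    continue  # direct edges are not constructs
                ok = True
                for c in path[1:-1]:
                    da, db, dc = depths.get(a), depths.get(b), depths.get(c)
                    if dc is None or da is None or db is None:
                        ok = False
                        break
                    if abs(dc - da) > granularity_delta or abs(dc - db) > granularity_delta:
                        ok = False
                        break
                if not ok:
                    continue
                rels = tuple(
                    trav.edges[u, v]["labels"][0] for u, v in zip(path, path[1:])
                )
                ckc = CKC(concepts=tuple(path), relations=rels)
                key = ckc.canonical()
                if key not in seen:
                    seen.add(key)
                    out.append(ckc)
    out.sort(key=lambda c: (len(c.concepts), c.concepts))
    return out


def ckc_network(
    ckcs: list[CKC],
    keep: "callable | None" = None,
) -> nx.Graph:
    """Aggregate kept CKC chains into the concept-layer network.

    ``keep`` is an optional predicate on a CKC (e.g. an annotation filter);
    edge multiplicity across chains collapses with the count retained as the
    ``weight`` attribute and the relation label kept on the edge.
    """
    g = nx.Graph(layer="conceptual")
    for ckc in ckcs:
        if keep is not None and not keep(ckc):
            continue
        for (u, v), rel in zip(zip(ckc.concepts, ckc.concepts[1:]), ckc.relations):
            if g.has_edge(u, v):
                g.edges[u, v]["weight"] += 1
            else:
                g.add_edge(u, v, relation=rel, weight=1)
    return g
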