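"""Readers and writers for the pipeline's plain-text interchange formats.

Formats: expression TSV (first column gene id, header row sample ids) with a
companion labels TSV; encounter CSV (empty field = null); ontology as a
concepts TSV + relations TSV pair, or minimal OBO; element-to-concept
mapping TSV; canonical edge-list TSV (lexicographically smaller node
first); Pajek .net (+ .clu partition); a small Graphviz DOT dialect with a
matching reader so exports round-trip; JSON result files.

Parsing is strict: dimension mismatches, duplicate ids and dangling
ontology references are reported with line numbers.
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .synthio import EncounterTable, ExpressionDataset, Ontology, VariableSpec

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_labels_tsv",
    "write_labels_tsv",
    "read_encounters_csv",
    "write_encounters_csv",
    "read_variable_specs_tsv",
    "write_variable_specs_tsv",
    "read_ontology_tsv",
    "write_ontology_tsv",
    "read_ontology_obo",
    "read_mapping_tsv",
    "write_mapping_tsv",
    "read_edge_list",
    "write_edge_list",
    "read_pajek",
    "write_pajek",
    "write_dot",
    "read_dot",
    "export_multinet",
    "write_json",
]


class FormatError(ValueError):
    """Structural error in an input file; message carries the line number."""


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def write_expression_tsv(ds: ExpressionDataset, path, labels_path=None) -> None:
    ds.to_frame().to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")
    if labels_path is not None and ds.labels is not None:
        write_labels_tsv(ds.labels, labels_path)


def read_expression_tsv(path, dataset_id=None, labels_path=None) -> ExpressionDataset:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}:1: expected gene_id column plus sample columns")
        sample_ids = header[1:]
        if len(set(sample_ids)) != len(sample_ids):
            raise FormatError(f"{path}:1: duplicate sample ids in header")
        genes, rows = [], []
        seen = set()
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            g = parts[0]
            if g in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {g!r}")
            seen.add(g)
            genes.append(g)
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: non-numeric value ({e})") from None
    labels = read_labels_tsv(labels_path) if labels_path else None
    return ExpressionDataset(
        dataset_id=dataset_id or path.stem,
        gene_ids=genes,
        sample_ids=sample_ids,
        values=np.array(rows, dtype=float),
        labels=labels,
    )


def write_labels_tsv(labels: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\n")
        for s in labels:
            fh.write(f"{s}\t{labels[s]}\n")


def read_labels_tsv(path) -> dict[str, int]:
    path = Path(path)
    labels: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sample_id"):
            raise FormatError(f"{path}:1: expected 'sample_id\\tlabel' header")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields")
            if parts[0] in labels:
                raise FormatError(f"{path}:{lineno}: duplicate sample id {parts[0]!r}")
            try:
                labels[parts[0]] = int(parts[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: label must be an integer") from None
    return labels


# ---------------------------------------------------------------------------
# encounters
# ---------------------------------------------------------------------------


def write_encounters_csv(tbl: EncounterTable, path) -> None:
    out = tbl.values.copy()
    out.insert(0, "encounter_id", tbl.encounter_ids)
    out.to_csv(path, index=False, na_rep="")


def read_encounters_csv(path, variables: list[VariableSpec]) -> EncounterTable:
    """Empty fields parse as null, never as an empty-string category."""
    path = Path(path)
    df = pd.read_csv(
        path, dtype=object, keep_default_na=False, na_values=[""], skip_blank_lines=False
    )
    if "encounter_id" not in df.columns:
        raise FormatError(f"{path}:1: missing 'encounter_id' column")
    ids = df["encounter_id"].tolist()
    dup = pd.Series(ids).duplicated()
    if dup.any():
        raise FormatError(
            f"{path}:{int(dup.idxmax()) + 2}: duplicate encounter id {ids[int(dup.idxmax())]!r}"
        )
    expected = [v.name for v in variables]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"{path}:1: missing variable columns {missing}")
    values = df[expected].copy()
    values.index = ids
    for v in variables:
        if v.kind == "continuous":
            values[v.name] = pd.to_numeric(values[v.name], errors="raise")
    return EncounterTable(encounter_ids=ids, variables=list(variables), values=values)


def write_variable_specs_tsv(variables: list[VariableSpec], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tkind\tcategories\tlow\thigh\tmapped_concept\n")
        for v in variables:
            cats = "|".join(v.categories) if v.categories else ""
            lo, hi = v.reference_range if v.reference_range else ("", "")
            fh.write(f"{v.name}\t{v.kind}\t{cats}\t{lo}\t{hi}\t{v.mapped_concept or ''}\n")


def read_variable_specs_tsv(path) -> list[VariableSpec]:
    path = Path(path)
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["name", "kind"]:
            raise FormatError(f"{path}:1: expected variable-spec header")
        for lineno, line in enumerate(fh, start=2):
            parts = (line.rstrip("\n").split("\t") + [""] * 6)[:6]
            name, kind, cats, lo, hi, concept = parts
            try:
                out.append(
                    VariableSpec(
                        name=name,
                        kind=kind,
                        categories=cats.split("|") if cats else None,
                        reference_range=(float(lo), float(hi)) if lo and hi else None,
                        mapped_concept=concept or None,
                    )
                )
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from None
    return out


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------


def write_ontology_tsv(onto: Ontology, concepts_path, relations_path) -> None:
    with open(concepts_path, "w") as fh:
        fh.write("id\tname\tsynonyms\tsemantic_type\n")
        for cid in sorted(onto.concepts):
            meta = onto.concepts[cid]
            fh.write(
                f"{cid}\t{meta['name']}\t{'|'.join(meta.get('synonyms', ()))}\t"
                f"{meta.get('semantic_type', '')}\n"
            )
    with open(relations_path, "w") as fh:
        fh.write("source\tlabel\ttarget\n")
        for s, lbl, t in sorted(onto.relations):
            fh.write(f"{s}\t{lbl}\t{t}\n")


def read_ontology_tsv(
    concepts_path, relations_path, isa_labels=("is_a",)
) -> Ontology:
    concepts_path, relations_path = Path(concepts_path), Path(relations_path)
    concepts: dict[str, dict] = {}
    with open(concepts_path) as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            parts = (line.rstrip("\n").split("\t") + [""] * 4)[:4]
            cid, name, syns, stype = parts
            if cid in concepts:
                raise FormatError(f"{concepts_path}:{lineno}: duplicate concept id {cid!r}")
            concepts[cid] = {
                "name": name,
                "synonyms": [s for s in syns.split("|") if s],
                "semantic_type": stype,
            }
    relations: set[tuple[str, str, str]] = set()
    with open(relations_path) as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise FormatError(f"{relations_path}:{lineno}: expected 3 fields")
            s, lbl, t = parts
            if s not in concepts or t not in concepts:
                raise FormatError(
                    f"{relations_path}:{lineno}: dangling concept reference ({s}, {t})"
                )
            relations.add((s, lbl, t))
    return Ontology(concepts=concepts, relations=relations, isa_labels=frozenset(isa_labels))


def read_ontology_obo(path) -> Ontology:
    """Minimal OBO loader (id / name / synonym / is_a / relationship
    stanzas), via obonet."""
    import obonet

    graph = obonet.read_obo(str(path))
    concepts: dict[str, dict] = {}
    relations: set[tuple[str, str, str]] = set()
    for cid, data in graph.nodes(data=True):
        syns = []
        for s in data.get("synonym", ()):
            m = re.match(r'"([^"]*)"', s)
            if m:
                syns.append(m.group(1))
        concepts[cid] = {
            "name": data.get("name", cid),
            "synonyms": syns,
            "semantic_type": data.get("namespace", ""),
        }
    for u, v, key in graph.edges(keys=True):
        relations.add((u, key, v))
    return Ontology(concepts=concepts, relations=relations, isa_labels=frozenset({"is_a"}))


def write_mapping_tsv(mapping: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("element_name\tconcept_id\n")
        for element in sorted(mapping):
            fh.write(f"{element}\t{mapping[element]}\n")


def read_mapping_tsv(path) -> dict[str, str]:
    path = Path(path)
    out: dict[str, str] = {}
    with open(path) as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields")
            if parts[0] in out:
                raise FormatError(f"{path}:{lineno}: duplicate element {parts[0]!r}")
            out[parts[0]] = parts[1]
    return out


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------


def write_edge_list(g: nx.Graph, path, attrs=("rho", "support")) -> None:
    """Canonical TSV edge list: lexicographically smaller node first."""
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b" + "".join(f"\t{a}" for a in attrs) + "\n")
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            data = g.edges[u, v]
            vals = "".join(f"\t{data.get(a, '')}" for a in attrs)
            fh.write(f"{u}\t{v}{vals}\n")


def read_edge_list(path) -> nx.Graph:
    path = Path(path)
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        attrs = header[2:]
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} fields")
            data = {}
            for a, raw in zip(attrs, parts[2:]):
                if raw == "":
                    continue
                try:
                    data[a] = float(raw) if "." in raw or "e" in raw else int(raw)
                except ValueError:
                    data[a] = raw
            g.add_edge(parts[0], parts[1], **data)
    return g


def write_pajek(g: nx.Graph, path, partition: dict | None = None, clu_path=None) -> None:
    """Pajek .net with an optional .clu partition file (one class per node,
    Pajek node order)."""
    relabeled = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
    # Pajek carries only string edge attributes
    for _u, _v, data in relabeled.edges(data=True):
        for k in list(data):
            if not isinstance(data[k], str):
                data[k] = repr(data[k])
    nx.write_pajek(relabeled, path)
    if partition is not None and clu_path is not None:
        nodes = list(relabeled.nodes)
        with open(clu_path, "w") as fh:
            fh.write(f"*Vertices {len(nodes)}\n")
            for n in nodes:
                fh.write(f"{partition.get(n, 0)}\n")


def read_pajek(path) -> nx.Graph:
    return nx.Graph(nx.read_pajek(str(path)))


_DOT_ID = re.compile(r"[^A-Za-z0-9_]")


def _dot_quote(s: str) -> str:
    return '"' + str(s).replace('"', r"\"") + '"'


def write_dot(mn, path) -> None:
    """Graphviz DOT with one subgraph cluster per layer and link_type as an
    edge attribute on cross-links."""
    lines = ["graph multinetwork {"]
    for name in sorted(mn.layers):
        layer = mn.layers[name]
        lines.append(f"  subgraph cluster_{_DOT_ID.sub('_', name)} {{")
        lines.append(f"    label={_dot_quote(name)};")
        for n in sorted(layer.graph.nodes):
            lines.append(f"    {_dot_quote(f'{name}::{n}')};")
        for u, v in sorted(tuple(sorted(e)) for e in layer.graph.edges):
            lines.append(
                f"    {_dot_quote(f'{name}::{u}')} -- {_dot_quote(f'{name}::{v}')};"
            )
        lines.append("  }")
    for cl in sorted(
        mn.cross_links, key=lambda c: (c.layer_a, c.node_a, c.layer_b, c.node_b)
    ):
        lines.append(
            f"  {_dot_quote(f'{cl.layer_a}::{cl.node_a}')} -- "
            f"{_dot_quote(f'{cl.layer_b}::{cl.node_b}')} "
            f'[link_type="{cl.link_type}"];'
        )
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


_DOT_EDGE = re.compile(
    r'^\s*"((?:[^"\\]|\\.)*)"\s*--\s*"((?:[^"\\]|\\.)*)"\s*(?:\[link_type="([^"]*)"\])?\s*;'
)
_DOT_NODE = re.compile(r'^\s*"((?:[^"\\]|\\.)*)"\s*;')


def read_dot(path):
    """Read the DOT dialect produced by :func:`write_dot` back into a
    MultiNetwork (within-layer edges and typed cross-links)."""
    from .vertint import CrossLink, LayerNetwork, MultiNetwork

    text = Path(path).read_text()
    layers: dict[str, nx.Graph] = {}
    cross: set[CrossLink] = set()

    def split(label: str) -> tuple[str, str]:
        layer, _, node = label.partition("::")
        return layer, node.replace(r"\"", '"')

    for line in text.splitlines():
        m = _DOT_EDGE.match(line)
        if m:
            (la, na), (lb, nb) = split(m.group(1)), split(m.group(2))
            if la == lb:
                layers.setdefault(la, nx.Graph()).add_edge(na, nb)
            else:
                cross.add(CrossLink(na, la, nb, lb, m.group(3) or "identical"))
            continue
        m = _DOT_NODE.match(line)
        if m and "::" in m.group(1):
            layer, node = split(m.group(1))
            layers.setdefault(layer, nx.Graph()).add_node(node)
    return MultiNetwork(
        layers={name: LayerNetwork(layer=name, graph=g) for name, g in layers.items()},
        cross_links=cross,
    )


def export_multinet(mn, path, fmt: str = "dot") -> None:
    """Write a multi-network as DOT or as Pajek .net + .clu layer partition."""
    path = Path(path)
    if fmt == "dot":
        write_dot(mn, path)
    elif fmt == "pajek":
        g = mn.union_graph()
        flat = nx.relabel_nodes(g, {n: f"{n[0]}::{n[1]}" for n in g.nodes})
        layer_index = {name: i for i, name in enumerate(sorted(mn.layers))}
        partition = {f"{n[0]}::{n[1]}": layer_index[n[0]] for n in g.nodes}
        write_pajek(flat, path, partition=partition, clu_path=path.with_suffix(".clu"))
    else:
        raise ValueError(f"unknown multi-network export format {fmt!r}")


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, np.generic):
            return o.item()
        if hasattr(o, "__dict__"):
            return o.__dict__
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default, sort_keys=True) + "\n")
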