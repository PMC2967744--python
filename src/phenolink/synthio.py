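"""Synthetic expression panels, clinical encounter tables, and toy ontologies.

These generators stand in for the remote/private sources the pipeline was
designed around (GEO expression series, a clinical data repository extract,
and licensed biomedical ontologies).  Each generator is a pure function of
its arguments including an integer seed, so every downstream stage is
reproducible at desk scale.

Expression model
----------------
Each planted module m is a single latent factor: for sample j the factor
value f_m(j) is standard normal, and a member gene g has

    x[g, j] = loading_g * f_m(j) + delta_g * label(j) + eps,   eps ~ N(0, sd_m)

with loading_g drawn uniformly from the module's loading range and delta_g
the phenotype effect size for designated effect genes.  Background genes are
pure N(0, 1) noise.  This gives direct control over within-module Pearson
correlation, which is the only structural assumption the gene-network stage
makes.

Encounter model
---------------
Correlated variable blocks are realized through a latent Gaussian copula:
the latent Pearson correlation for a Spearman target rho_s is
2*sin(pi*rho_s/6), categorical values are produced by thresholding latents
at equal-probability quantiles, and nulls are placed completely at random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "ModuleSpec",
    "EncounterTable",
    "VariableSpec",
    "Ontology",
    "gen_expression_panel",
    "gen_encounter_table",
    "gen_ontology",
    "spearman_to_latent_pearson",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """One genes x samples expression matrix with optional binary labels."""

    dataset_id: str
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)
    labels: dict[str, int] | None = None  # sample_id -> 0/1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique within a dataset")
        if self.labels is not None:
            missing = set(self.sample_ids) - set(self.labels)
            if missing:
                raise ValueError(f"labels missing for samples: {sorted(missing)}")

    def expression(self, gene: str) -> np.ndarray:
        try:
            return self.values[self.gene_ids.index(gene)]
        except ValueError:
            raise KeyError(f"gene {gene!r} not in dataset {self.dataset_id}") from None

    def label_vector(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError(f"dataset {self.dataset_id} has no phenotype labels")
        return np.array([self.labels[s] for s in self.sample_ids], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ModuleSpec:
    """Parameters of one planted co-expression module.

    effect_genes designates which members get a phenotype mean shift of
    effect_size between label groups; by default every member does when
    effect_size is nonzero.
    """

    member_genes: list[str]
    latent_loading_range: tuple[float, float] = (0.8, 1.2)
    effect_size: float = 0.0
    noise_sd: float = 1.0
    effect_genes: list[str] | None = None

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        lo, hi = self.latent_loading_range
        if lo > hi:
            raise ValueError("latent_loading_range must be (low, high) with low <= high")
        if self.effect_genes is not None:
            extra = set(self.effect_genes) - set(self.member_genes)
            if extra:
                raise ValueError(f"effect_genes not in member_genes: {sorted(extra)}")

    def resolved_effect_genes(self) -> list[str]:
        if self.effect_genes is not None:
            return list(self.effect_genes)
        return list(self.member_genes) if self.effect_size != 0 else []


@dataclass
class VariableSpec:
    """One clinical variable: categorical with declared categories, or
    continuous with an optional (low, high) reference range."""

    name: str
    kind: str  # "categorical" | "continuous"
    categories: list[str] | None = None
    reference_range: tuple[float, float] | None = None
    mapped_concept: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.categories:
                raise ValueError(f"categorical variable {self.name!r} needs categories")
        if self.reference_range is not None:
            lo, hi = self.reference_range
            if not lo < hi:
                raise ValueError(
                    f"reference_range for {self.name!r} must satisfy low < high"
                )


@dataclass
class EncounterTable:
    """Encounter x variable table; entries may be null (NaN/None)."""

    encounter_ids: list[str]
    variables: list[VariableSpec]
    values: pd.DataFrame  # index = encounter_ids, columns = variable names

    def __post_init__(self) -> None:
        if len(set(self.encounter_ids)) != len(self.encounter_ids):
            raise ValueError("encounter_ids must be unique")
        expected = [v.name for v in self.variables]
        if list(self.values.columns) != expected:
            raise ValueError("values columns must match variable names in order")
        for v in self.variables:
            if v.kind == "categorical":
                col = self.values[v.name].dropna()
                bad = set(col) - set(v.categories)
                if bad:
                    raise ValueError(
                        f"variable {v.name!r} has undeclared categories: {sorted(bad)}"
                    )


@dataclass
class Ontology:
    """Concepts plus directed typed relation triples; a subset of relation
    labels (isa_labels) forms the acyclic hierarchy."""

    concepts: dict[str, dict] = field(default_factory=dict)
    # concept id -> {"name": str, "synonyms": [str], "semantic_type": str}
    relations: set[tuple[str, str, str]] = field(default_factory=set)
    isa_labels: frozenset[str] = frozenset({"is_a"})

    def __post_init__(self) -> None:
        self.isa_labels = frozenset(self.isa_labels)
        for s, _lbl, t in self.relations:
            if s not in self.concepts or t not in self.concepts:
                raise ValueError(f"relation endpoint not a concept: ({s}, {t})")
        self._check_hierarchy_acyclic()

    def _check_hierarchy_acyclic(self) -> None:
        import networkx as nx

        g = self.isa_graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("hierarchical (is-a) subgraph contains a cycle")

    def isa_graph(self):
        """Directed child -> parent graph restricted to hierarchical labels."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.concepts)
        g.add_edges_from(
            (s, t) for s, lbl, t in self.relations if lbl in self.isa_labels
        )
        return g

    def name_of(self, cid: str) -> str:
        return self.concepts[cid]["name"]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def gen_expression_panel(
    n_datasets: int,
    n_genes: int,
    n_samples: int,
    modules: list[ModuleSpec],
    anchor_genes: set[str] | None = None,
    seed: int = 0,
    label_fraction: float = 0.5,
) -> list[ExpressionDataset]:
    """Generate a panel of independent expression datasets sharing one gene
    universe, with planted latent-factor co-expression modules.

    Genes are named G0000..G{n-1} unless module specs name them explicitly;
    module member names are injected into the shared universe.  Each dataset
    gets its own latent factors, loadings and noise, but the module structure
    (membership, effect genes) is shared — emulating a collection of
    independent studies measuring the same biology.
    """
    if n_datasets <= 0 or n_genes <= 0 or n_samples <= 0:
        raise ValueError("n_datasets, n_genes and n_samples must be positive")
    seen: set[str] = set()
    for m in modules:
        overlap = seen & set(m.member_genes)
        if overlap:
            raise ValueError(
                f"module memberships overlap on genes: {sorted(overlap)}"
            )
        seen |= set(m.member_genes)
    anchor_genes = set(anchor_genes or ())
    if anchor_genes and not anchor_genes <= seen:
        raise ValueError("anchor genes must belong to some module")

    gene_ids = _gene_universe(n_genes, modules)
    if len(gene_ids) != n_genes:
        raise ValueError(
            f"module member names exceed the requested universe of {n_genes} genes"
        )
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    rng = np.random.default_rng(seed)
    n_pos = int(round(label_fraction * n_samples))
    panel: list[ExpressionDataset] = []
    for d in range(n_datasets):
        sample_ids = [f"D{d}S{j}" for j in range(n_samples)]
        # same group sizes each dataset; assignment shuffled per dataset
        label_vec = np.zeros(n_samples, dtype=int)
        label_vec[:n_pos] = 1
        rng.shuffle(label_vec)
        values = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
        for m in modules:
            factor = rng.standard_normal(n_samples)
            lo, hi = m.latent_loading_range
            loadings = rng.uniform(lo, hi, size=len(m.member_genes))
            effect = set(m.resolved_effect_genes())
            for g, loading in zip(m.member_genes, loadings):
                row = loading * factor + rng.normal(0.0, m.noise_sd, n_samples)
                if g in effect:
                    row = row + m.effect_size * label_vec
                values[gene_index[g]] = row
        panel.append(
            ExpressionDataset(
                dataset_id=f"DS{d}",
                gene_ids=list(gene_ids),
                sample_ids=sample_ids,
                values=values,
                labels={s: int(v) for s, v in zip(sample_ids, label_vec)},
            )
        )
    return panel


def _gene_universe(n_genes: int, modules: list[ModuleSpec]) -> list[str]:
    named = [g for m in modules for g in m.member_genes]
    n_background = n_genes - len(named)
    if n_background < 0:
        return named  # caller raises
    background = []
    i = 0
    named_set = set(named)
    while len(background) < n_background:
        g = f"G{i:04d}"
        if g not in named_set:
            background.append(g)
        i += 1
    universe = named + background
    return sorted(universe)


def spearman_to_latent_pearson(rho_s: float) -> float:
    """Latent Pearson correlation realizing a Spearman target under a
    bivariate Gaussian copula: r = 2*sin(pi*rho_s/6)."""
    if not -1.0 < rho_s < 1.0:
        raise ValueError("target Spearman rho must lie in (-1, 1)")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def gen_encounter_table(
    n_encounters: int,
    variables: list[VariableSpec],
    block_corr: list[tuple[set[str], float]] | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> EncounterTable:
    """Generate an encounter table with optional correlated variable blocks
    and missing-completely-at-random nulls."""
    if n_encounters <= 0:
        raise ValueError("n_encounters must be positive")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    block_corr = block_corr or []
    names = [v.name for v in variables]
    name_to_var = {v.name: v for v in variables}
    claimed: set[str] = set()
    for block, rho in block_corr:
        unknown = set(block) - set(names)
        if unknown:
            raise ValueError(f"block names not among variables: {sorted(unknown)}")
        if claimed & set(block):
            raise ValueError("block variable sets must be disjoint")
        claimed |= set(block)
        spearman_to_latent_pearson(rho)  # validates range

    rng = np.random.default_rng(seed)
    latent = pd.DataFrame(
        rng.standard_normal((n_encounters, len(names))), columns=names
    )
    for block, rho in block_corr:
        members = [n for n in names if n in block]
        k = len(members)
        r = spearman_to_latent_pearson(rho)
        cov = np.full((k, k), r)
        np.fill_diagonal(cov, 1.0)
        latent[members] = rng.multivariate_normal(
            np.zeros(k), cov, size=n_encounters, method="cholesky"
        )

    from scipy.stats import norm

    cols: dict[str, object] = {}
    for name in names:
        var = name_to_var[name]
        z = latent[name].to_numpy()
        if var.kind == "continuous":
            if var.reference_range is not None:
                lo, hi = var.reference_range
                mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
                cols[name] = mid + z * half  # roughly 68% in range
            else:
                cols[name] = z
        else:
            k = len(var.categories)
            edges = norm.ppf(np.linspace(0, 1, k + 1)[1:-1])
            codes = np.searchsorted(edges, z)
            cols[name] = pd.Categorical.from_codes(
                codes, categories=var.categories
            ).astype(object)

    encounter_ids = [f"E{i:05d}" for i in range(n_encounters)]
    table = pd.DataFrame(cols, index=encounter_ids)[names]
    if missing_rate > 0:
        mask = rng.random(table.shape) < missing_rate
        table = table.mask(mask)
    return EncounterTable(encounter_ids=encounter_ids, variables=list(variables), values=table)


# small vocabulary for synthetic concept names; mapping tests rely only on
# token overlap, not on these particular words
_NAME_TOKENS = [
    "cell", "protein", "marker", "assay", "count", "serum", "tissue",
    "antigen", "receptor", "kinase", "lymphoid", "plasma", "membrane",
    "factor", "binding", "expression", "pathway", "clinical", "blood",
    "enzyme",
]


def gen_ontology(
    n_concepts: int,
    branching: int,
    n_crosslinks: int,
    associative_labels: list[str] | None = None,
    seed: int = 0,
) -> tuple[Ontology, dict[str, str]]:
    """Generate a rooted is-a tree plus random associative cross-links, and a
    data-dictionary-element -> leaf-concept mapping.

    The tree is filled in breadth-first order (node i's parent is node
    (i-1) // branching), so a complete b-ary shape is produced whenever
    n_concepts allows one.  Synonyms are token permutations of the preferred
    name; mapping element names reuse the leaf concept's tokens so lexical
    matching has signal to find.
    """
    if n_concepts <= 0 or branching <= 0 or n_crosslinks < 0:
        raise ValueError("n_concepts and branching must be positive; n_crosslinks >= 0")
    associative_labels = list(associative_labels or ["associated_with"])
    rng = np.random.default_rng(seed)

    concepts: dict[str, dict] = {}
    relations: set[tuple[str, str, str]] = set()
    ids = [f"C{i:04d}" for i in range(n_concepts)]
    for i, cid in enumerate(ids):
        k = 2 + int(rng.integers(0, 2))
        toks = list(rng.choice(_NAME_TOKENS, size=k, replace=False))
        name = " ".join([f"term{i}"] + toks)
        words = name.split()
        synonyms = []
        if len(words) > 1:
            perm = words[::-1]
            if perm != words:
                synonyms.append(" ".join(perm))
        concepts[cid] = {
            "name": name,
            "synonyms": synonyms,
            "semantic_type": "synthetic_concept",
        }
        if i > 0:
            parent = ids[(i - 1) // branching]
            relations.add((cid, "is_a", parent))

    children: dict[str, int] = {}
    for s, lbl, t in relations:
        children[t] = children.get(t, 0) + 1
    leaves = [c for c in ids if c not in children]

    for _ in range(n_crosslinks):
        a, b = rng.choice(n_concepts, size=2, replace=False)
        lbl = associative_labels[int(rng.integers(0, len(associative_labels)))]
        relations.add((ids[int(a)], lbl, ids[int(b)]))

    onto = Ontology(concepts=concepts, relations=relations, isa_labels=frozenset({"is_a"}))

    mapping: dict[str, str] = {}
    for cid in leaves:
        toks = concepts[cid]["name"].split()
        element = "_".join(toks[:2]) + "_field"
        mapping[element] = cid
    return onto, mapping
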