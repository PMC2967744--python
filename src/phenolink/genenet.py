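"""Gene co-expression network induction and mining.

The stage mirrors a multi-dataset co-expression workflow: per-gene Pearson
correlations against anchor genes, hypergeometric overlap testing of anchor
gene lists between datasets, per-dataset co-expression graphs at a
|rho| threshold, a summary graph of edges supported by at least
``min_support`` datasets, greedy mining of dense subgraphs (connectivity
ratio r = L / (n(n-1)/2) above a floor), a coherence filter on the mined
modules' cross-dataset edge-support profiles, and finally differential
expression plus holdout classification of module genes against a binary
phenotype.

The dense-subgraph miner is deterministic: minimum-degree peeling with
lexicographic tie-breaking, retention of the best-density snapshot seen
during the peel, and recursive re-mining of the leftover vertices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .synthio import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "GeneCorrelationList",
    "IntersectionResult",
    "DenseModule",
    "DEResult",
    "ClassifierReport",
    "pearson",
    "anchor_list",
    "overlap_test",
    "build_graph",
    "summary_graph",
    "mine_dense",
    "coherence_filter",
    "connectivity_ratio",
    "differential_expression",
    "holdout_eval",
]


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------


@dataclass
class GeneCorrelationList:
    """Genes correlated with an anchor gene past a threshold, one dataset."""

    anchor: str
    dataset_id: str
    threshold: float
    sign: str  # "positive" | "negative"
    members: dict[str, float]  # gene -> Pearson rho vs anchor

    @property
    def genes(self) -> set[str]:
        return set(self.members)


@dataclass
class IntersectionResult:
    size_a: int
    size_b: int
    overlap: int
    universe: int
    p_value: float
    overlap_genes: set[str] = field(default_factory=set)


@dataclass
class DenseModule:
    genes: list[str]  # sorted
    edges: set[frozenset]
    connectivity_ratio: float
    coherence: float | None = None

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def L(self) -> int:
        return len(self.edges)


@dataclass
class DEResult:
    genes: list[str]
    t: dict[str, float]
    p: dict[str, float]
    group_means: dict[str, tuple[float, float]]
    alpha: float
    significant_set: set[str]
    adjusted: bool = False


@dataclass
class ClassifierReport:
    accuracy: float
    per_repeat: list[float]
    holdout_fraction: float
    n_repeats: int
    seed: int


# ---------------------------------------------------------------------------
# correlations and anchor lists
# ---------------------------------------------------------------------------


def pearson(x, y) -> float:
    """Product-moment correlation; raises on constant or short input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def _corr_matrix(ds: ExpressionDataset) -> tuple[np.ndarray, list[str]]:
    """All-pairs Pearson matrix over non-constant genes."""
    keep = [i for i in range(len(ds.gene_ids)) if np.ptp(ds.values[i]) > 0]
    dropped = len(ds.gene_ids) - len(keep)
    if dropped:
        logger.warning(
            "dataset %s: skipped %d constant-expression genes", ds.dataset_id, dropped
        )
    genes = [ds.gene_ids[i] for i in keep]
    mat = np.corrcoef(ds.values[keep])
    return mat, genes


def anchor_list(
    ds: ExpressionDataset, anchor: str, threshold: float, sign: str = "positive"
) -> GeneCorrelationList:
    """Genes whose correlation with the anchor passes ``threshold`` with the
    requested sign; the anchor itself is excluded."""
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    a = ds.expression(anchor)  # KeyError if absent
    if np.ptp(a) == 0:
        raise ValueError(f"anchor {anchor!r} has constant expression")
    members: dict[str, float] = {}
    for g, row in zip(ds.gene_ids, ds.values):
        if g == anchor or np.ptp(row) == 0:
            continue
        rho = pearson(a, row)
        if sign == "positive" and rho >= threshold:
            members[g] = rho
        elif sign == "negative" and rho <= -threshold:
            members[g] = rho
    return GeneCorrelationList(
        anchor=anchor,
        dataset_id=ds.dataset_id,
        threshold=threshold,
        sign=sign,
        members=members,
    )


def overlap_test(list_a, list_b, universe: int) -> IntersectionResult:
    """One-sided (over-representation) hypergeometric test of gene-list
    overlap: P(X >= overlap) drawing |b| from a universe containing |a|
    successes.  Accepts gene sets, or (size, size, overlap) via
    :func:`overlap_test_counts`."""
    a, b = set(list_a), set(list_b)
    if universe < len(a | b):
        raise ValueError("universe smaller than the union of the two lists")
    inter = a & b
    res = overlap_test_counts(len(a), len(b), len(inter), universe)
    res.overlap_genes = inter
    return res


def overlap_test_counts(
    size_a: int, size_b: int, overlap: int, universe: int
) -> IntersectionResult:
    if overlap > min(size_a, size_b):
        raise ValueError("overlap cannot exceed either list size")
    if max(size_a, size_b) > universe:
        raise ValueError("list sizes cannot exceed the universe")
    p = float(stats.hypergeom.sf(overlap - 1, universe, size_a, size_b))
    return IntersectionResult(
        size_a=size_a,
        size_b=size_b,
        overlap=overlap,
        universe=universe,
        p_value=min(p, 1.0),
    )


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------


def build_graph(ds: ExpressionDataset, threshold: float) -> nx.Graph:
    """Per-dataset co-expression graph: edge (g, h) iff |rho(g, h)| >=
    threshold; edge attribute ``rho`` holds the signed coefficient."""
    if len(ds.sample_ids) < 3:
        raise ValueError("need at least 3 samples to correlate")
    mat, genes = _corr_matrix(ds)
    g = nx.Graph(dataset_id=ds.dataset_id)
    g.add_nodes_from(genes)
    idx = np.argwhere(np.triu(np.abs(mat) >= threshold, k=1))
    for i, j in idx:
        g.add_edge(genes[i], genes[j], rho=float(mat[i, j]))
    return g


def summary_graph(graphs: list[nx.Graph], min_support: int) -> nx.Graph:
    """Edges present in at least ``min_support`` component graphs.

    Edge attributes: ``support`` (dataset count), ``rho`` (mean coefficient
    over supporting datasets), ``datasets`` (sorted supporting dataset ids,
    used later by the coherence filter).
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if len(graphs) < min_support:
        raise ValueError("fewer graphs supplied than min_support")
    tally: dict[frozenset, list[tuple[str, float]]] = {}
    for k, g in enumerate(graphs):
        did = g.graph.get("dataset_id", f"graph{k}")
        for u, v, data in g.edges(data=True):
            tally.setdefault(frozenset((u, v)), []).append((did, data.get("rho", np.nan)))
    out = nx.Graph()
    for pair, hits in tally.items():
        if len(hits) >= min_support:
            u, v = sorted(pair)
            out.add_edge(
                u,
                v,
                support=len(hits),
                rho=float(np.mean([r for _, r in hits])),
                datasets=tuple(sorted(d for d, _ in hits)),
            )
    return out


def connectivity_ratio(n: int, L: int) -> float:
    """r = L / (n(n-1)/2), the edge density of a simple subgraph."""
    if n < 2:
        raise ValueError("need at least 2 nodes")
    maximum = n * (n - 1) // 2
    if not 0 <= L <= maximum:
        raise ValueError(f"L={L} outside [0, {maximum}] for n={n}")
    return 2.0 * L / (n * (n - 1))


def _subgraph_module(g: nx.Graph, nodes) -> DenseModule:
    sub = g.subgraph(nodes)
    return DenseModule(
        genes=sorted(sub.nodes),
        edges={frozenset(e) for e in sub.edges},
        connectivity_ratio=connectivity_ratio(sub.number_of_nodes(), sub.number_of_edges()),
    )


def _peel_best(g: nx.Graph, min_size: int) -> tuple[list, float] | None:
    """Min-degree peel with lexicographic tie-break; return the snapshot
    (node set, r) of highest density with >= min_size nodes, preferring the
    larger set on density ties."""
    work = g.copy()
    best: tuple[float, int, list] | None = None
    order = 0
    while work.number_of_nodes() >= min_size:
        n, L = work.number_of_nodes(), work.number_of_edges()
        r = connectivity_ratio(n, L)
        cand = (r, n, sorted(work.nodes))
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
        victim = min(work.nodes, key=lambda v: (work.degree(v), v))
        work.remove_node(victim)
        order += 1
    if best is None:
        return None
    return best[2], best[0]


def mine_dense(graph: nx.Graph, min_r: float, min_size: int = 3) -> list[DenseModule]:
    """Greedy extraction of dense subgraphs with connectivity ratio > min_r.

    Each connected component is peeled by minimum degree (ties broken by
    lexicographic gene order) while tracking the density of every remaining
    set; the densest snapshot of size >= min_size is emitted as a module if
    its r exceeds min_r, its vertices are removed, and the remainder is
    re-mined — so one component can split into several modules.  Output is
    sorted by (descending size, lexicographic gene list).
    """
    if not 0 < min_r <= 1:
        raise ValueError("min_r must lie in (0, 1]")
    if min_size < 3:
        raise ValueError("min_size must be >= 3")
    modules: list[DenseModule] = []
    stack = [graph.subgraph(c).copy() for c in nx.connected_components(graph)]
    while stack:
        comp = stack.pop()
        if comp.number_of_nodes() < min_size:
            continue
        found = _peel_best(comp, min_size)
        if found is None:
            continue
        nodes, r = found
        if r <= min_r:
            continue
        modules.append(_subgraph_module(graph, nodes))
        rest = comp.copy()
        rest.remove_nodes_from(nodes)
        stack.extend(rest.subgraph(c).copy() for c in nx.connected_components(rest))
    modules.sort(key=lambda m: (-m.n, m.genes))
    return modules


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def module_coherence(module: DenseModule, summary: nx.Graph) -> float:
    """Mean pairwise Jaccard similarity of the module edges' dataset-support
    sets (taken from the summary graph's ``datasets`` attribute)."""
    supports = []
    for e in sorted(module.edges, key=sorted):
        u, v = sorted(e)
        supports.append(frozenset(summary.edges[u, v].get("datasets", ())))
    if len(supports) < 2:
        return 1.0
    sims = [
        _jaccard(supports[i], supports[j])
        for i in range(len(supports))
        for j in range(i + 1, len(supports))
    ]
    return float(np.mean(sims))


def coherence_filter(
    modules: list[DenseModule], summary: nx.Graph, min_coherence: float
) -> list[DenseModule]:
    """Keep modules whose edges co-occur in similar sets of datasets."""
    kept = []
    for m in modules:
        c = module_coherence(m, summary)
        m.coherence = c
        if c >= min_coherence:
            kept.append(m)
    return kept


# ---------------------------------------------------------------------------
# phenotype association
# ---------------------------------------------------------------------------


def differential_expression(
    ds: ExpressionDataset,
    genes,
    alpha: float = 0.05,
    adjust: bool = False,
) -> DEResult:
    """Welch two-sample t-test per gene between the two label groups.

    ``adjust=True`` applies Benjamini-Hochberg to the p-values before
    thresholding at alpha.
    """
    labels = ds.label_vector()
    g0 = labels == 0
    g1 = labels == 1
    if g0.sum() < 2 or g1.sum() < 2:
        raise ValueError("each label group needs at least 2 samples")
    genes = sorted(genes)
    missing = [g for g in genes if g not in ds.gene_ids]
    if missing:
        raise KeyError(f"genes not in dataset: {missing}")
    t: dict[str, float] = {}
    p: dict[str, float] = {}
    means: dict[str, tuple[float, float]] = {}
    for g in genes:
        x = ds.expression(g)
        res = stats.ttest_ind(x[g1], x[g0], equal_var=False)
        t[g] = float(res.statistic)
        p[g] = float(res.pvalue)
        means[g] = (float(x[g0].mean()), float(x[g1].mean()))
    pvals = np.array([p[g] for g in genes])
    if adjust:
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        sig = {g for g, r in zip(genes, reject) if r}
    else:
        sig = {g for g, pv in zip(genes, pvals) if pv < alpha}
    return DEResult(
        genes=genes, t=t, p=p, group_means=means, alpha=alpha,
        significant_set=sig, adjusted=adjust,
    )


def _dlda_fit(X: np.ndarray, y: np.ndarray):
    """Diagonal linear discriminant: per-gene class means and pooled
    per-gene variance."""
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    n0, n1 = (y == 0).sum(), (y == 1).sum()
    v0 = X[y == 0].var(axis=0, ddof=1) if n0 > 1 else np.zeros(X.shape[1])
    v1 = X[y == 1].var(axis=0, ddof=1) if n1 > 1 else np.zeros(X.shape[1])
    pooled = ((n0 - 1) * v0 + (n1 - 1) * v1) / max(n0 + n1 - 2, 1)
    pooled = np.where(pooled <= 0, 1e-12, pooled)
    return mu0, mu1, pooled


def _dlda_predict(X: np.ndarray, mu0, mu1, pooled) -> np.ndarray:
    d0 = ((X - mu0) ** 2 / pooled).sum(axis=1)
    d1 = ((X - mu1) ** 2 / pooled).sum(axis=1)
    return (d1 < d0).astype(int)


def holdout_eval(
    ds: ExpressionDataset,
    genes,
    holdout: float = 0.2,
    n_repeats: int = 50,
    seed: int = 0,
) -> ClassifierReport:
    """Repeated stratified holdout evaluation of a diagonal linear
    discriminant trained on the given gene set.

    Each repeat draws a stratified random holdout of the requested fraction
    (at least one sample per class held out), trains on the remainder, and
    scores holdout accuracy; the report carries the per-repeat accuracies
    and their mean.
    """
    if not 0 < holdout < 1:
        raise ValueError("holdout fraction must lie in (0, 1)")
    labels = ds.label_vector()
    if len(set(labels)) < 2:
        raise ValueError("both classes must be present")
    genes = sorted(genes)
    rows = [ds.gene_ids.index(g) for g in genes]
    X = ds.values[rows].T  # samples x genes
    y = labels
    rng = np.random.default_rng(seed)
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    k0 = max(1, int(round(holdout * idx0.size)))
    k1 = max(1, int(round(holdout * idx1.size)))
    if k0 >= idx0.size or k1 >= idx1.size:
        raise ValueError("holdout fraction leaves an empty training class")
    accs = []
    for _ in range(n_repeats):
        test = np.concatenate(
            [rng.choice(idx0, k0, replace=False), rng.choice(idx1, k1, replace=False)]
        )
        mask = np.zeros(y.size, dtype=bool)
        mask[test] = True
        mu0, mu1, pooled = _dlda_fit(X[~mask], y[~mask])
        pred = _dlda_predict(X[mask], mu0, mu1, pooled)
        accs.append(float((pred == y[mask]).mean()))
    return ClassifierReport(
        accuracy=float(np.mean(accs)),
        per_repeat=accs,
        holdout_fraction=holdout,
        n_repeats=n_repeats,
        seed=seed,
    )
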