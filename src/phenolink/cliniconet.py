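"""Clinical feature correlation network.

Clinical variables are first binned to ordinal codes: categorical variables
one code per declared category (range-merged down to ``max_cats`` bins when
there are more categories than that), continuous variables against a
(low, high) reference range into below / within / above normal, or into
tertiles when no range exists.  Pairwise Spearman rank correlations are then
computed over pairwise-complete (both non-null) observations, declared
undefined below a minimum pair count rather than silently zero, and the
network keeps attribute pairs whose correlation clears a high threshold.
A log-log least-squares fit of the degree histogram summarizes whether the
network is scale-free-like.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .synthio import EncounterTable, VariableSpec

logger = logging.getLogger(__name__)

__all__ = [
    "BinnedTable",
    "ClinicalNetwork",
    "DegreeFit",
    "bin_variable",
    "bin_table",
    "spearman_pair",
    "build_network",
    "degree_fit",
    "fit_degree_histogram",
    "top_hubs",
]


@dataclass
class BinnedTable:
    encounter_ids: list[str]
    codes: pd.DataFrame  # ordinal codes, nullable Int64 columns
    dictionaries: dict[str, dict[int, str]]  # attr -> code -> label

    @property
    def attributes(self) -> list[str]:
        return list(self.codes.columns)


@dataclass
class ClinicalNetwork:
    graph: nx.Graph  # edge attrs: rho, n_pairs
    undefined_pairs: set[frozenset] = field(default_factory=set)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)


@dataclass
class DegreeFit:
    histogram: list[tuple[int, int]]  # (degree, node count), degree >= 1
    slope: float
    intercept: float
    fit_R: float


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def bin_variable(
    values: pd.Series, spec: VariableSpec, max_cats: int = 8
) -> tuple[pd.Series, dict[int, str]]:
    """Bin one raw column to ordinal codes (nullable Int64); nulls propagate.

    Categorical: one code per declared category in declared order; with more
    than ``max_cats`` categories, contiguous category ranges are merged into
    ``max_cats`` near-equal bins.  Continuous with a reference range
    (low, high): 0 below low, 1 within [low, high], 2 above high.
    Continuous without a range: tertiles.
    """
    if spec.kind == "categorical":
        cats = list(spec.categories)
        if len(cats) <= max_cats:
            code_of = {c: i for i, c in enumerate(cats)}
            dictionary = {i: c for i, c in enumerate(cats)}
        else:
            # split the declared order into max_cats contiguous ranges whose
            # category counts differ by at most one
            base, extra = divmod(len(cats), max_cats)
            code_of, dictionary, start = {}, {}, 0
            for b in range(max_cats):
                width = base + (1 if b < extra else 0)
                chunk = cats[start : start + width]
                for c in chunk:
                    code_of[c] = b
                dictionary[b] = f"{chunk[0]}..{chunk[-1]}" if len(chunk) > 1 else chunk[0]
                start += width
        bad = [v for v in values.dropna().unique() if v not in code_of]
        if bad:
            raise ValueError(
                f"variable {spec.name!r}: undeclared categories {sorted(map(str, bad))}"
            )
        coded = values.map(lambda v: code_of.get(v, pd.NA)).astype("Int64")
        return coded, dictionary

    # continuous
    numeric = pd.to_numeric(values, errors="coerce")
    offending = values.notna() & numeric.isna()
    if offending.any():
        name = values.index[offending][0]
        raise ValueError(
            f"variable {spec.name!r}: non-numeric value "
            f"{values[offending].iloc[0]!r} at entry {name!r}"
        )
    if spec.reference_range is not None:
        lo, hi = spec.reference_range
        coded = pd.Series(pd.NA, index=values.index, dtype="Int64")
        coded[numeric < lo] = 0
        coded[(numeric >= lo) & (numeric <= hi)] = 1
        coded[numeric > hi] = 2
        return coded, {0: "below normal", 1: "normal", 2: "above normal"}
    # tertiles over observed values
    binned = pd.qcut(numeric, 3, labels=False, duplicates="drop")
    coded = pd.Series(binned, index=values.index).astype("Int64")
    labels = {0: "low tertile", 1: "mid tertile", 2: "high tertile"}
    n_bins = int(coded.max()) + 1 if coded.notna().any() else 0
    return coded, {k: labels[k] for k in range(n_bins)}


def bin_table(tbl: EncounterTable, max_cats: int = 8) -> BinnedTable:
    cols, dicts = {}, {}
    for var in tbl.variables:
        coded, d = bin_variable(tbl.values[var.name], var, max_cats=max_cats)
        cols[var.name] = coded
        dicts[var.name] = d
    return BinnedTable(
        encounter_ids=list(tbl.encounter_ids),
        codes=pd.DataFrame(cols, index=tbl.values.index),
        dictionaries=dicts,
    )


# ---------------------------------------------------------------------------
# correlation network
# ---------------------------------------------------------------------------


def spearman_pair(x: pd.Series, y: pd.Series, min_pairs: int = 20):
    """Spearman rho over pairwise-complete observations, or None when fewer
    than ``min_pairs`` remain or a restricted column is constant.

    Returns (rho, n_pairs); rho is None when undefined.
    """
    if len(x) != len(y):
        raise ValueError("columns must have equal length")
    xv = pd.to_numeric(pd.Series(x).reset_index(drop=True), errors="coerce")
    yv = pd.to_numeric(pd.Series(y).reset_index(drop=True), errors="coerce")
    both = xv.notna() & yv.notna()
    n = int(both.sum())
    if n < min_pairs:
        return None, n
    xs, ys = xv[both].to_numpy(dtype=float), yv[both].to_numpy(dtype=float)
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        logger.warning("constant column after pairwise restriction; rho undefined")
        return None, n
    rho = stats.spearmanr(xs, ys).statistic
    return float(rho), n


def prefilter_attributes(tbl: BinnedTable, min_pairs: int = 20) -> BinnedTable:
    """Drop attributes that can never form a defined correlation: fewer than
    ``min_pairs`` non-null entries overall, or constant after binning."""
    keep = []
    for a in tbl.attributes:
        col = tbl.codes[a]
        obs = col.dropna()
        if len(obs) < min_pairs or obs.nunique() < 2:
            continue
        keep.append(a)
    dropped = len(tbl.attributes) - len(keep)
    if dropped:
        logger.info("prefilter dropped %d of %d attributes", dropped, len(tbl.attributes))
    return BinnedTable(
        encounter_ids=tbl.encounter_ids,
        codes=tbl.codes[keep],
        dictionaries={a: tbl.dictionaries[a] for a in keep},
    )


def build_network(
    tbl: BinnedTable,
    rho_min: float = 0.95,
    min_pairs: int = 20,
    use_absolute: bool = False,
) -> ClinicalNetwork:
    """Threshold the pairwise-complete Spearman matrix into a network.

    By default only rho >= rho_min pairs become edges; ``use_absolute``
    switches to |rho| >= rho_min.  Pairs failing the minimum-pair rule are
    recorded as undefined, never treated as zero.
    """
    attrs = tbl.attributes
    if len(attrs) < 2:
        raise ValueError("need at least 2 attributes")
    g = nx.Graph()
    g.add_nodes_from(attrs)
    undefined: set[frozenset] = set()
    for i, a in enumerate(attrs):
        for b in attrs[i + 1 :]:
            rho, n = spearman_pair(tbl.codes[a], tbl.codes[b], min_pairs=min_pairs)
            if rho is None:
                undefined.add(frozenset((a, b)))
                continue
            score = abs(rho) if use_absolute else rho
            if score >= rho_min:
                g.add_edge(a, b, rho=rho, n_pairs=n)
    return ClinicalNetwork(graph=g, undefined_pairs=undefined)


def correlation_matrix(tbl: BinnedTable, min_pairs: int = 20) -> pd.DataFrame:
    """Full symmetric Spearman matrix with NaN for undefined pairs (diagonal 1)."""
    attrs = tbl.attributes
    mat = pd.DataFrame(np.nan, index=attrs, columns=attrs)
    for a in attrs:
        mat.loc[a, a] = 1.0
    for i, a in enumerate(attrs):
        for b in attrs[i + 1 :]:
            rho, _ = spearman_pair(tbl.codes[a], tbl.codes[b], min_pairs=min_pairs)
            if rho is not None:
                mat.loc[a, b] = mat.loc[b, a] = rho
    return mat


# ---------------------------------------------------------------------------
# degree statistics
# ---------------------------------------------------------------------------


def degree_fit(net: ClinicalNetwork | nx.Graph) -> DegreeFit:
    """Least-squares line through (log10 degree, log10 count) over the
    nonzero-count bins of the degree histogram (degree >= 1)."""
    g = net.graph if isinstance(net, ClinicalNetwork) else net
    degrees = [d for _, d in g.degree() if d >= 1]
    if not degrees:
        raise ValueError("degree fit undefined: no connected nodes")
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    return fit_degree_histogram(sorted(hist.items()))


def fit_degree_histogram(pts: list[tuple[int, float]]) -> DegreeFit:
    """Fit log10(count) ~ log10(degree) over nonzero-count histogram bins."""
    pts = [(d, c) for d, c in pts if c > 0]
    if len(pts) < 2:
        raise ValueError("degree fit undefined: fewer than 2 distinct degrees")
    lx = np.log10([d for d, _ in pts])
    ly = np.log10([c for _, c in pts])
    res = stats.linregress(lx, ly)
    return DegreeFit(
        histogram=pts,
        slope=float(res.slope),
        intercept=float(res.intercept),
        fit_R=float(res.rvalue),
    )


def top_hubs(net: ClinicalNetwork | nx.Graph, k: int = 10) -> list[tuple[str, int]]:
    """Attributes ranked by degree descending, ties lexicographic."""
    g = net.graph if isinstance(net, ClinicalNetwork) else net
    ranked = sorted(g.degree(), key=lambda item: (-item[1], item[0]))
    if k > len(ranked):
        logger.info("k=%d exceeds node count %d; returning full ranking", k, len(ranked))
    return [(a, int(d)) for a, d in ranked[:k]]
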