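"""Gene co-expression stage: correlations, overlap testing, summary-graph
mining and phenotype association, each checked against an independent
brute-force oracle at small scale."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from phenolink import genenet, synthio
from phenolink.genenet import (
    anchor_list,
    build_graph,
    coherence_filter,
    connectivity_ratio,
    differential_expression,
    holdout_eval,
    mine_dense,
    module_coherence,
    overlap_test,
    overlap_test_counts,
    pearson,
    summary_graph,
)
from phenolink.synthio import ExpressionDataset, ModuleSpec

from conftest import two_cliques_bridge


# ---------------------------------------------------------------------------
# pearson / anchor lists
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ((1, 2, 3), (2, 4, 6), 1.0),
        ((1, 2, 3), (6, 4, 2), -1.0),
        ((1, 2, 3, 4), (1, 3, 2, 4), 0.8),  # hand evaluation of the definition
    ],
)
def test_pearson_known_values(x, y, expected):
    assert pearson(x, y) == pytest.approx(expected)


def test_pearson_rejects_constant_and_short():
    with pytest.raises(ValueError, match="constant"):
        pearson([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        pearson([1, 2], [3, 4])


def test_anchor_list_zero_noise_module_is_complete():
    module = ModuleSpec(
        member_genes=[f"M{i}" for i in range(5)],
        latent_loading_range=(1.0, 1.0),
        noise_sd=1e-9,
    )
    ds = synthio.gen_expression_panel(1, 12, 30, [module], seed=0)[0]
    lst = anchor_list(ds, "M0", 0.4, "positive")
    assert {f"M{i}" for i in range(1, 5)} <= lst.genes
    assert "M0" not in lst.genes


def test_anchor_list_impossible_threshold_empty(small_panel):
    assert anchor_list(small_panel[0], "M0", 1.01, "positive").genes == set()


def test_anchor_list_matches_bruteforce(small_panel):
    ds = small_panel[0]
    a = ds.expression("M0")
    for sign in ("positive", "negative"):
        lst = anchor_list(ds, "M0", 0.4, sign)
        expect = {}
        for g in ds.gene_ids:
            if g == "M0":
                continue
            rho = stats.pearsonr(a, ds.expression(g)).statistic
            if (sign == "positive" and rho >= 0.4) or (sign == "negative" and rho <= -0.4):
                expect[g] = rho
        assert lst.genes == set(expect)
        for g, r in lst.members.items():
            assert r == pytest.approx(expect[g])
        if sign == "positive":
            assert all(r >= 0.4 for r in lst.members.values())
        else:
            assert all(r <= -0.4 for r in lst.members.values())


def test_anchor_absent_raises(small_panel):
    with pytest.raises(KeyError):
        anchor_list(small_panel[0], "NOPE", 0.4)


# ---------------------------------------------------------------------------
# overlap test
# ---------------------------------------------------------------------------


def enumerate_overlap_p(size_a, size_b, overlap, universe):
    """Exact upper-tail probability by enumerating every possible draw."""
    pop = range(universe)
    a = set(range(size_a))
    hits = total = 0
    for draw in itertools.combinations(pop, size_b):
        total += 1
        if len(a & set(draw)) >= overlap:
            hits += 1
    return hits / total


def test_overlap_small_example_equals_point_mass_sum():
    # sizes (4, 3), overlap 2, universe 10
    res = overlap_test_counts(4, 3, 2, 10)
    expected = sum(
        math.comb(4, k) * math.comb(6, 3 - k) / math.comb(10, 3) for k in (2, 3)
    )
    assert res.p_value == pytest.approx(expected)


@pytest.mark.parametrize(
    "size_a, size_b, overlap, universe",
    [(4, 3, 2, 10), (5, 5, 1, 12), (6, 4, 4, 11), (3, 7, 0, 9), (2, 2, 2, 8)],
)
def test_overlap_matches_full_enumeration(size_a, size_b, overlap, universe):
    res = overlap_test_counts(size_a, size_b, overlap, universe)
    assert res.p_value == pytest.approx(
        enumerate_overlap_p(size_a, size_b, overlap, universe)
    )


def test_overlap_p_nonincreasing_in_overlap():
    ps = [overlap_test_counts(20, 15, k, 100).p_value for k in range(0, 16)]
    assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))


def test_overlap_accepts_gene_sets():
    res = overlap_test({"a", "b", "c"}, {"b", "c", "d"}, 10)
    assert res.overlap == 2
    assert res.overlap_genes == {"b", "c"}


def test_overlap_universe_too_small_rejected():
    with pytest.raises(ValueError):
        overlap_test({"a", "b"}, {"c", "d"}, 3)


# ---------------------------------------------------------------------------
# graphs and mining
# ---------------------------------------------------------------------------


def test_build_graph_zero_noise_clique():
    module = ModuleSpec(
        member_genes=list("ABCD"), latent_loading_range=(1.0, 1.0), noise_sd=1e-9
    )
    ds = synthio.gen_expression_panel(1, 8, 20, [module], seed=1)[0]
    g = build_graph(ds, 0.99)
    assert g.subgraph(list("ABCD")).number_of_edges() == 6


def test_build_graph_matches_allpairs_filter(small_panel):
    ds = small_panel[0]
    g = build_graph(ds, 0.75)
    expect = set()
    for ga, gb in itertools.combinations(ds.gene_ids, 2):
        rho = stats.pearsonr(ds.expression(ga), ds.expression(gb)).statistic
        if abs(rho) >= 0.75:
            expect.add(frozenset((ga, gb)))
    assert {frozenset(e) for e in g.edges} == expect


def test_summary_graph_support_rule():
    graphs = []
    for k in range(6):
        g = nx.Graph(dataset_id=f"DS{k}")
        if k < 4:
            g.add_edge("A", "B", rho=0.8)
        g.add_edge("C", "D", rho=0.9)
        graphs.append(g)
    s = summary_graph(graphs, min_support=4)
    assert s.edges["A", "B"]["support"] == 4
    assert s.edges["C", "D"]["support"] == 6
    s5 = summary_graph(graphs, min_support=5)
    assert not s5.has_edge("A", "B")
    union = summary_graph(graphs, min_support=1)
    assert set(map(frozenset, union.edges)) == {frozenset("AB"), frozenset("CD")}
    with pytest.raises(ValueError):
        summary_graph(graphs, min_support=7)


def test_summary_graph_monotone_in_support():
    rng = np.random.default_rng(0)
    graphs = []
    for k in range(6):
        g = nx.Graph(dataset_id=f"DS{k}")
        for i, j in itertools.combinations(range(8), 2):
            if rng.random() < 0.5:
                g.add_edge(f"g{i}", f"g{j}", rho=1.0)
        graphs.append(g)
    prev = None
    for ms in range(1, 7):
        edges = set(map(frozenset, summary_graph(graphs, ms).edges))
        if prev is not None:
            assert edges <= prev
        prev = edges


@pytest.mark.parametrize(
    "n, L, expected", [(3, 3, 1.0), (3, 2, 2 / 3), (6, 7, 7 / 15)]
)
def test_connectivity_ratio_formula(n, L, expected):
    assert connectivity_ratio(n, L) == pytest.approx(expected)


def test_connectivity_ratio_rejects_overfull():
    with pytest.raises(ValueError):
        connectivity_ratio(4, 7)


def oracle_mine(graph, min_r, min_size):
    """Exhaustive recursive extraction of the maximum-density subset
    (ties: larger set, then lexicographically smallest)."""
    out = []
    stack = [graph.subgraph(c).copy() for c in nx.connected_components(graph)]
    while stack:
        comp = stack.pop()
        nodes = sorted(comp.nodes)
        if len(nodes) < min_size:
            continue
        best = None
        for k in range(min_size, len(nodes) + 1):
            for sub in itertools.combinations(nodes, k):
                sg = comp.subgraph(sub)
                r = 2 * sg.number_of_edges() / (k * (k - 1))
                cand = (-r, -k, list(sub))
                if best is None or cand < best:
                    best = cand
        if best is None or -best[0] <= min_r:
            continue
        chosen = best[2]
        out.append(frozenset(chosen))
        rest = comp.copy()
        rest.remove_nodes_from(chosen)
        stack.extend(rest.subgraph(c).copy() for c in nx.connected_components(rest))
    return set(out)


def test_mine_dense_clique_with_isolates():
    g = nx.Graph()
    g.add_edges_from(itertools.combinations([f"c{i}" for i in range(5)], 2))
    g.add_nodes_from(f"iso{i}" for i in range(10))
    mods = mine_dense(g, 0.4, 3)
    assert len(mods) == 1
    assert mods[0].genes == [f"c{i}" for i in range(5)]
    assert mods[0].connectivity_ratio == 1.0


def test_mine_dense_splits_bridged_cliques():
    mods = mine_dense(two_cliques_bridge(), 0.4, 3)
    assert {frozenset(m.genes) for m in mods} == {
        frozenset(f"a{i}" for i in range(4)),
        frozenset(f"b{i}" for i in range(4)),
    }
    assert oracle_mine(two_cliques_bridge(), 0.4, 3) == {
        frozenset(m.genes) for m in mods
    }


def oracle_signature(graph, min_r, min_size):
    """(r, size) sequence of the exhaustive recursive optimal extraction."""
    out = []
    stack = [graph.subgraph(c).copy() for c in nx.connected_components(graph)]
    while stack:
        comp = stack.pop()
        nodes = sorted(comp.nodes)
        if len(nodes) < min_size:
            continue
        best = None
        for k in range(min_size, len(nodes) + 1):
            for sub in itertools.combinations(nodes, k):
                sg = comp.subgraph(sub)
                r = 2 * sg.number_of_edges() / (k * (k - 1))
                cand = (-r, -k, list(sub))
                if best is None or cand < best:
                    best = cand
        if best is None or -best[0] <= min_r:
            continue
        out.append((round(-best[0], 9), -best[1]))
        rest = comp.copy()
        rest.remove_nodes_from(best[2])
        stack.extend(rest.subgraph(c).copy() for c in nx.connected_components(rest))
    return sorted(out)


def _battery():
    """Structured <= 12-node motifs the miner is designed to resolve."""
    graphs = []
    g = nx.Graph()
    g.add_edges_from(itertools.combinations("abcde", 2))
    g.add_nodes_from("fghij")
    graphs.append(("clique_plus_isolates", g))
    graphs.append(("two_cliques_bridge", two_cliques_bridge()))
    graphs.append(("barbell", nx.relabel_nodes(nx.barbell_graph(4, 2), str)))
    shared = nx.Graph()
    shared.add_edges_from(itertools.combinations("abcd", 2))
    shared.add_edges_from(itertools.combinations("defg", 2))
    graphs.append(("cliques_sharing_vertex", shared))
    graphs.append(("cycle", nx.relabel_nodes(nx.cycle_graph(8), str)))
    graphs.append(("star", nx.relabel_nodes(nx.star_graph(7), str)))
    graphs.append(("path", nx.relabel_nodes(nx.path_graph(9), str)))
    return graphs


def _er_graphs():
    out = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        g = nx.Graph()
        g.add_nodes_from(f"n{i:02d}" for i in range(10))
        for i, j in itertools.combinations(range(10), 2):
            if rng.random() < 0.35:
                g.add_edge(f"n{i:02d}", f"n{j:02d}")
        out.append((f"er10_seed{seed}", g))
    return out


@pytest.mark.parametrize("name, graph", _battery())
@pytest.mark.parametrize("min_r", [0.4, 0.6])
def test_mine_dense_matches_exhaustive_oracle(name, graph, min_r):
    """On structured motifs the greedy extraction reaches exactly the
    optimal decomposition found by exhaustive subset search; where several
    equally dense decompositions exist the (r, size) signature must agree."""
    mods = mine_dense(graph, min_r, 3)
    for m in mods:
        assert m.connectivity_ratio > min_r
        assert m.connectivity_ratio == connectivity_ratio(m.n, m.L)
    sig = sorted((round(m.connectivity_ratio, 9), m.n) for m in mods)
    assert sig == oracle_signature(graph, min_r, 3)
    if name in ("clique_plus_isolates", "two_cliques_bridge", "barbell"):
        assert {frozenset(m.genes) for m in mods} == oracle_mine(graph, min_r, 3)


@pytest.mark.parametrize("name, graph", _er_graphs())
def test_mine_dense_random_graph_invariants(name, graph):
    """On unstructured random graphs the greedy modules must all qualify,
    be vertex-disjoint, and never exceed the exhaustive optimum density."""
    min_r = 0.4
    mods = mine_dense(graph, min_r, 3)
    claimed: set[str] = set()
    for m in mods:
        assert m.connectivity_ratio > min_r
        assert m.connectivity_ratio == connectivity_ratio(m.n, m.L)
        assert not claimed & set(m.genes)
        claimed |= set(m.genes)
        for e in m.edges:
            assert graph.has_edge(*sorted(e))
    osig = oracle_signature(graph, min_r, 3)
    if mods and osig:
        assert max(m.connectivity_ratio for m in mods) <= osig[-1][0] + 1e-9


def test_mine_dense_empty_graph():
    assert mine_dense(nx.Graph(), 0.4, 3) == []


# ---------------------------------------------------------------------------
# coherence
# ---------------------------------------------------------------------------


def _summary_with_supports(edge_supports):
    g = nx.Graph()
    for (u, v), datasets in edge_supports.items():
        g.add_edge(u, v, datasets=tuple(sorted(datasets)), support=len(datasets))
    return g


def test_coherence_identical_support_is_one():
    s = _summary_with_supports(
        {("a", "b"): {"d1", "d2"}, ("b", "c"): {"d1", "d2"}, ("a", "c"): {"d1", "d2"}}
    )
    mod = mine_dense(s, 0.4, 3)[0]
    assert module_coherence(mod, s) == 1.0


def test_coherence_disjoint_support_is_zero():
    s = _summary_with_supports({("a", "b"): {"d1"}, ("b", "c"): {"d2"}, ("a", "c"): {"d1"}})
    mod = mine_dense(s, 0.4, 3)[0]
    # pairwise Jaccards: (ab,bc)=0, (ab,ac)=1, (ac,bc)=0 -> mean 1/3
    assert module_coherence(mod, s) == pytest.approx(1 / 3)


def test_coherence_equals_hand_enumerated_jaccards():
    rng = np.random.default_rng(42)
    datasets = [f"d{i}" for i in range(6)]
    edges = [("a", "b"), ("b", "c"), ("c", "d"), ("a", "c"), ("b", "d")]
    supports = {
        e: set(rng.choice(datasets, size=rng.integers(1, 5), replace=False))
        for e in edges
    }
    s = _summary_with_supports(supports)
    mod = mine_dense(s, 0.4, 3)[0]
    vecs = [
        frozenset(supports[e])
        for e in sorted((frozenset(e) for e in mod.edges), key=sorted)
        for e in [tuple(sorted(e))]
    ]
    expected = np.mean(
        [
            len(a & b) / len(a | b)
            for a, b in itertools.combinations(vecs, 2)
        ]
    )
    assert module_coherence(mod, s) == pytest.approx(expected)


def test_coherence_filter_keeps_and_annotates():
    s = _summary_with_supports(
        {("a", "b"): {"d1"}, ("b", "c"): {"d1"}, ("a", "c"): {"d1"}}
    )
    mods = mine_dense(s, 0.4, 3)
    kept = coherence_filter(mods, s, min_coherence=0.9)
    assert kept and kept[0].coherence == 1.0
    s2 = _summary_with_supports(
        {("a", "b"): {"d1"}, ("b", "c"): {"d2"}, ("a", "c"): {"d3"}}
    )
    assert coherence_filter(mine_dense(s2, 0.4, 3), s2, min_coherence=0.5) == []


# ---------------------------------------------------------------------------
# phenotype association
# ---------------------------------------------------------------------------


def _labeled_dataset(effect, noise, n_per_group=50, seed=0, n_genes=10):
    module = ModuleSpec(
        member_genes=[f"M{i}" for i in range(5)],
        latent_loading_range=(0.9, 1.1),
        effect_size=effect,
        noise_sd=noise,
    )
    return synthio.gen_expression_panel(
        1, n_genes, 2 * n_per_group, [module], seed=seed
    )[0]


def test_de_planted_effect_detected_across_seeds():
    hits = 0
    for seed in range(20):
        ds = _labeled_dataset(effect=1.5, noise=0.5, seed=seed)
        de = differential_expression(ds, [f"M{i}" for i in range(5)])
        hits += len(de.significant_set) == 5
    assert hits >= 19  # planted shift of 3 noise sd detected in >= 95% of seeds


def test_de_type_one_error_near_alpha():
    n_sig = n_tot = 0
    for seed in range(10):
        ds = _labeled_dataset(effect=0.0, noise=1.0, seed=seed, n_genes=40)
        background = [g for g in ds.gene_ids if not g.startswith("M")]
        de = differential_expression(ds, background, alpha=0.05)
        n_sig += len(de.significant_set)
        n_tot += len(background)
    rate = n_sig / n_tot
    se = math.sqrt(0.05 * 0.95 / n_tot)
    assert abs(rate - 0.05) < 4 * se


def test_de_group_stats_match_direct_ttest():
    ds = _labeled_dataset(effect=1.0, noise=0.5, seed=3)
    de = differential_expression(ds, ["M0"])
    y = ds.label_vector()
    x = ds.expression("M0")
    ref = stats.ttest_ind(x[y == 1], x[y == 0], equal_var=False)
    assert de.t["M0"] == pytest.approx(ref.statistic)
    assert de.p["M0"] == pytest.approx(ref.pvalue)


def test_de_requires_two_per_group():
    ds = _labeled_dataset(effect=1.0, noise=0.5, seed=0)
    ds.labels = {s: (1 if i == 0 else 0) for i, s in enumerate(ds.sample_ids)}
    with pytest.raises(ValueError):
        differential_expression(ds, ["M0"])


def test_holdout_perfect_separation():
    ds = _labeled_dataset(effect=50.0, noise=0.01, seed=1)
    rep = holdout_eval(ds, [f"M{i}" for i in range(5)], 0.2, 10, seed=0)
    assert rep.accuracy == 1.0


def test_holdout_null_labels_near_chance():
    accs = []
    for seed in range(10):
        ds = _labeled_dataset(effect=0.0, noise=1.0, seed=seed)
        rep = holdout_eval(ds, [f"M{i}" for i in range(5)], 0.2, 20, seed=seed)
        accs.append(rep.accuracy)
    mean = np.mean(accs)
    se = np.std(accs, ddof=1) / math.sqrt(len(accs))
    assert abs(mean - 0.5) < max(3 * se, 0.1)


def test_holdout_informative_genes_beat_random_sets():
    rng = np.random.default_rng(7)
    diffs = []
    for seed in range(20):
        ds = _labeled_dataset(effect=1.5, noise=0.5, seed=seed, n_genes=30)
        planted = [f"M{i}" for i in range(5)]
        background = [g for g in ds.gene_ids if not g.startswith("M")]
        rand = list(rng.choice(background, size=5, replace=False))
        a = holdout_eval(ds, planted, 0.2, 10, seed=seed).accuracy
        b = holdout_eval(ds, rand, 0.2, 10, seed=seed).accuracy
        diffs.append(a - b)
    assert np.mean(diffs) > 0
    assert np.mean([d >= 0 for d in diffs]) >= 0.9
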