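import networkx as nx
import pytest

from phenolink import synthio


@pytest.fixture
def small_panel():
    """Six datasets, 30 genes, one planted 6-gene module, mild noise."""
    module = synthio.ModuleSpec(
        member_genes=[f"M{i}" for i in range(6)],
        latent_loading_range=(0.9, 1.1),
        effect_size=2.0,
        noise_sd=0.3,
    )
    return synthio.gen_expression_panel(
        n_datasets=6, n_genes=30, n_samples=40, modules=[module],
        anchor_genes={"M0"}, seed=11,
    )


@pytest.fixture
def toy_ontology():
    """Complete binary tree of 7 concepts plus one associative cross-link."""
    onto, mapping = synthio.gen_ontology(
        n_concepts=7, branching=2, n_crosslinks=1,
        associative_labels=["associated_with"], seed=3,
    )
    return onto, mapping


def two_cliques_bridge() -> nx.Graph:
    g = nx.Graph()
    for base in ("a", "b"):
        nodes = [f"{base}{i}" for i in range(4)]
        g.add_edges_from(
            (nodes[i], nodes[j]) for i in range(4) for j in range(i + 1, 4)
        )
    g.add_edge("a0", "b0")
    return g
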