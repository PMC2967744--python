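"""Packaged demonstration fixture: a three-layer multi-network whose
vertical complex joins a gene co-expression path, a five-concept knowledge
chain, and a four-node clinical correlation path.

The fixture encodes the published worked example for chronic lymphocytic
leukemia: the gene path CD8A - IL2RB - ZAP70, the knowledge chain

    [ZAP70 gene] -gene_plays_role_in_process- [Ligand Binding]
    -biological_process_involves_gene_product- [LTB4R protein, human]
    -gene_product_expressed_in_tissue- [Lymphoid Tissue]
    -is_normal_tissue_origin_of_disease- [Chronic lymphocytic leukaemia refractory]

and the clinical path

    Chronic lymphocytic leukemia refractory (treatment response)
    - del(17p13) - CLL with unmutated IgVH - Lactic acid dehydrogenase raised

cross-linked at the shared ZAP70 and refractory-CLL concepts.
"""

from __future__ import annotations

import networkx as nx

from .synthio import Ontology
from .vertint import LayerNetwork, MultiNetwork, cross_link

__all__ = [
    "worked_example_ontology",
    "worked_example_layers",
    "worked_example_multinetwork",
    "GENE_PATH",
    "CKC_CHAIN",
    "CKC_RELATIONS",
    "CLINICAL_PATH",
]

GENE_PATH = ["CD8A", "IL2RB", "ZAP70"]

CKC_CHAIN = [
    "ZAP70_GENE",
    "LIGAND_BINDING",
    "LTB4R_PROTEIN",
    "LYMPHOID_TISSUE",
    "CLL_REFRACTORY",
]

CKC_RELATIONS = [
    "gene_plays_role_in_process",
    "biological_process_involves_gene_product",
    "gene_product_expressed_in_tissue",
    "is_normal_tissue_origin_of_disease",
]

CLINICAL_PATH = [
    "Chronic lymphocytic leukemia refractory (treatment response)",
    "del(17p13)",
    "CLL with unmutated IgVH",
    "Lactic acid dehydrogenase raised",
]

_CONCEPT_NAMES = {
    "ZAP70_GENE": "ZAP70 gene",
    "LIGAND_BINDING": "Ligand Binding",
    "LTB4R_PROTEIN": "LTB4R protein, human",
    "LYMPHOID_TISSUE": "Lymphoid Tissue",
    "CLL_REFRACTORY": "Chronic lymphocytic leukaemia refractory",
}


def worked_example_ontology() -> Ontology:
    concepts = {
        cid: {"name": name, "synonyms": [], "semantic_type": ""}
        for cid, name in _CONCEPT_NAMES.items()
    }
    relations = {
        (a, rel, b)
        for (a, b), rel in zip(zip(CKC_CHAIN, CKC_CHAIN[1:]), CKC_RELATIONS)
    }
    return Ontology(concepts=concepts, relations=relations, isa_labels=frozenset({"is_a"}))


def worked_example_layers() -> dict[str, LayerNetwork]:
    gene = nx.Graph()
    nx.add_path(gene, GENE_PATH)

    conceptual = nx.Graph()
    for (a, b), rel in zip(zip(CKC_CHAIN, CKC_CHAIN[1:]), CKC_RELATIONS):
        conceptual.add_edge(a, b, relation=rel)

    clinical = nx.Graph()
    nx.add_path(clinical, CLINICAL_PATH)

    return {
        "gene": LayerNetwork(
            layer="gene", graph=gene, concept_of={"ZAP70": "ZAP70_GENE"}
        ),
        "conceptual": LayerNetwork(layer="conceptual", graph=conceptual),
        "clinical": LayerNetwork(
            layer="clinical",
            graph=clinical,
            concept_of={CLINICAL_PATH[0]: "CLL_REFRACTORY"},
        ),
    }


def worked_example_multinetwork() -> MultiNetwork:
    """Layers plus the semantic cross-links found by pairwise evaluation
    (identical-concept links at ZAP70 and at the refractory-CLL concept)."""
    return cross_link(worked_example_layers(), worked_example_ontology())
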