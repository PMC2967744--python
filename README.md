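# phenolink

Multi-layer biomarker–phenotype network discovery for translational
research data. `phenolink` induces three networks at different levels of
granularity and cross-links them into "vertical" complexes that join
bio-molecular markers to clinical phenotypes:

1. **Gene co-expression layer** — Pearson correlation (ρ) anchor gene
   lists at |ρ| ≥ 0.4 with hypergeometric overlap testing between
   expression series; per-dataset co-expression graphs at |ρ| ≥ 0.75; a
   summary graph of edges supported by ≥ 4 datasets; greedy mining of
   coherent dense subgraphs with connectivity ratio
   *r = L / (n(n−1)/2) > 0.4*; Welch-t differential expression and
   diagonal-linear-discriminant classification with 20% sample holdout
   against a binary phenotype (e.g. IgVH mutation status in CLL).
2. **Clinical feature layer** — clinical variables binned to ordinal
   codes (reference ranges → below/normal/above; ≤ 8 categorical bins),
   pairwise-complete Spearman rank correlation with a minimum of 20
   non-null pairs (pairs below the minimum are *undefined*, never zero),
   thresholded at ρ ≥ 0.95, with a log-log degree-histogram fit to assess
   scale-free structure.
3. **Conceptual knowledge layer** — data-dictionary elements lexically
   mapped onto an ontology; *constructive induction* enumerates
   conceptual knowledge constructs (CKCs): simple relation chains between
   mapped concepts routed through unmapped intermediate concepts, with a
   granularity filter on is-a depth.

The integration stage evaluates **semantic links** (identical concept,
direct parent–child, shared-parent sibling) between the conceptual layer
and the other two, and extracts vertical complexes — simple paths through
the union of within-layer edges and cross-links that span multiple layers.

A fully seeded synthetic-data module (`phenolink.synthio`) generates
expression panels with planted latent-factor modules, encounter tables
with Gaussian-copula-correlated variable blocks, and toy ontologies, so
the whole pipeline is exercisable and testable at desk scale.

## Worked example

The packaged fixture (`phenolink.demo`) encodes a known chronic
lymphocytic leukemia vertical complex: a gene path, a five-concept
knowledge chain, and a clinical correlation path, joined at the shared
ZAP70 and refractory-CLL concepts.

```python
from phenolink import demo, vertint

mn = demo.worked_example_multinetwork()
complexes = vertint.extract_complexes(mn, "gene", "clinical", max_len=12)
full = max(complexes, key=len)
print(len(full), sorted(full.layers_spanned))
print(" -> ".join(node for _, node in full.nodes))
```

prints

```
11 ['clinical', 'conceptual', 'gene']
CD8A -> IL2RB -> ZAP70 -> ZAP70_GENE -> LIGAND_BINDING -> LTB4R_PROTEIN -> LYMPHOID_TISSUE -> CLL_REFRACTORY -> Chronic lymphocytic leukemia refractory (treatment response) -> del(17p13) -> CLL with unmutated IgVH -> Lactic acid dehydrogenase raised
```

— an 11-hop complex spanning all three layers from a cytotoxic-T-cell
marker gene to a raised lactate dehydrogenase phenotype.

The full pipeline on synthetic inputs:

```sh
phenolink run-all --out-dir results --seed 1
```

or step by step through the numbered drivers:

```sh
python analysis/01_simulate.py 1
python analysis/02_gene_network.py 1
python analysis/03_clinical_network.py 1
python analysis/04_concept_network.py 1
python analysis/05_integrate.py 1
```

The gene-network driver prints, among other things,

```
mined 1 coherent dense module(s); top module 10 genes,
10 differentially expressed, holdout accuracy 0.895
```

meaning the planted 10-gene module was recovered intact from the
6-dataset summary graph, every member is differentially expressed between
the planted phenotype groups, and the module predicts the phenotype well
above the 0.5 majority baseline on repeated 20% holdouts.

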