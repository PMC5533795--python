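# diagnet

Integrated diagnostic-network construction from multi-cohort gene-expression
data and protein–protein interactions.

Cancer subtyping panels built from single-cohort differential expression are
notoriously unstable. `diagnet` implements a network-based route to compact
diagnostic gene panels, developed around breast-cancer subtyping (ER/PR/HER2
status): candidate genes are scored per cohort, condensed into per-cohort
*diagnostic networks* on a protein-interaction graph, integrated into a
consensus network across cohorts, and distilled to a handful of *pivotal*
genes whose interactions concentrate in the consensus network. The package is
aimed at computational biologists who want each stage — and the whole
pipeline — as tested, reusable building blocks, exercisable end-to-end on
synthetic data with planted ground truth.

## Method

For gene *g* in one cohort with tumor (group 1) and normal (group 2) samples,
differential expression is scored with the Welch-type statistic

    t_g = (X̄_g1 − X̄_g2) / √(S²_g1/n₁ + S²_g2/n₂),

with unbiased group variances; two-sided p-values (Welch–Satterthwaite df)
are Benjamini–Hochberg adjusted within the candidate set, and genes below the
cutoff are the cohort's diagnostic diff-genes. On the subnetwork they induce
in the interaction graph, a greedy active-module search grows a module from
every seed gene, maximizing a node-score aggregate (default Σ|t|/√k); the
top-10 modules are merged and the search repeated on the merged subgraph
until the node count reaches ≈50. Genes and edges present in ≥3 of the
per-cohort diagnostic networks form the integrated diagnostic network, with
pairwise overlap quantified as 100·|∩| / (Σ sizes − |∩|).

Pivotal genes are selected by connectivity enrichment
EC_j = C_s,j / C_D,j (consensus-network degree over background degree), with
a quartile-based degree-representation analysis Per_i = N_s,i / N_D,i and a
1000-draw permutation test for the top degree quartile; sharp drops in the
ranked EC sequence bound the candidate panel sizes. Panels are evaluated by
stratified 10-fold and leave-one-out cross-validation of four-class receptor
subtype prediction (native k-NN, k = 10; any fit/predict classifier plugs
in), per-gene subtype stratification t-tests, and hierarchical-clustering
leaf order. Gene-set enrichment of the consensus genes reports the Fisher
exact p, BH-adjusted p, rank-deviation Z against seeded random queries, and
the combined score C = log₁₀(p)·Z.

## Worked example

The one-command synthetic demo plants a 40-gene module (4 pivotal genes)
in a 400-gene interaction graph, simulates six 30+30 case/control cohorts,
and runs every stage:

```sh
diagnet run --outdir demo --seed 1
```

or in Python:

```python
from diagnet.pipeline import run_pipeline, default_demo_config
result = run_pipeline(default_demo_config(seed=1), "demo")
```

With seed 1 the run completes with `status: ok` and its output files
(`demo/`, all listed with checksums in `demo/manifest.json`) contain:

```
consensus: 44 genes, 79 edges
top EC genes: G0033, G0214, G0323, G0155  (EC = 0.900, 0.889, 0.889, 0.800)
breakpoint after position 4; candidate panel of size 4
permutation p (top degree quartile): 0.000999
top enriched term: PLANTED_MODULE (p = 1.4e-45, C = 71.6)
```

The four top-EC genes are exactly the planted pivotal genes
(`demo/inputs/truth.json`), the permutation test confirms the consensus
network is hub-enriched far beyond chance, and the planted module is the top
enriched gene set. The 4-gene panel reaches mean stratified 10-fold k-NN
accuracies of 0.77–0.88 across the six simulated cohorts
(`demo/cv_report.tsv`) on four-class subtype prediction — chance is ≈0.32.

Each stage is also a subcommand (`simulate`, `score`, `search`, `integrate`,
`pivotal`, `enrich`, `evaluate`) reading and writing plain TSV/JSON/GMT, so
real cohort matrices and a BioGRID TAB3 interactome drop into the same flow.

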