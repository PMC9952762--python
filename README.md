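# omicsforest

De novo network enrichment for two-condition multi-omics studies:
differential abundance across transcript, protein and metabolite layers;
geneset and metabolite-pathway enrichment; and extraction of perturbed
subnetworks from a merged gene–metabolite interaction network via a
prize-collecting Steiner forest (PCSF), with community decomposition and
prize-density ranking.

It is written for the common situation where a gene of unclear function has
been knocked out in a cell line, all three omics layers have been profiled
in wild-type (WT) and knockout (KO) replicates, and the question is *which
cellular processes moved* — including processes that no curated pathway
describes, which is exactly what pathway-free network enrichment is for.

## The model

Every measured feature gets a KO-vs-WT log2 fold change; a feature measured
in several layers keeps its largest absolute value as its node **prize**
p(v) on the global interaction graph (unquantified nodes get 0). Each edge
carries a confidence s ∈ (0, 1] and a traversal cost c(e) = 1 − s. The PCSF
stage selects a forest F minimizing

```
Obj(F) = β · Σ_{v ∉ F} p'(v)  +  Σ_{e ∈ F} c(e)  +  ω · κ
```

where p'(v) = max(0, p(v) − μ·deg(v)) is the hub-penalized prize, κ is the
number of trees, and β, ω, μ are the prize scale, the per-tree opening
penalty and the hub penalty. Zero-prize nodes kept only to connect prized
ones are **Steiner nodes** — the mechanism by which unquantified genes enter
the result. The solver reduces the forest problem to a rooted Steiner tree
(virtual root joined to every prized node at cost ω), grows
Goemans–Williamson moats, strong-prunes, and polishes with deterministic
local search; `brute_force_pcsf` provides the exact optimum for instances
up to 15 nodes.

The solution is then broken into communities (greedy modularity), each
community is tested for pathway over-representation (hypergeometric, BH),
and communities with best-pathway FDR < 0.05 are ranked by **prize
density** D(S) = Σ_{v∈S} p(v) / (|S| / N) — collected prize per fraction of
the global network consumed.

Upstream, the package implements gene-level TPM aggregation, NSAF
(normalized spectral abundance factor) quantification for spectral counts,
Welch-on-log2 differential testing with BH FDR (externally computed
differential tables with the same columns can be imported instead),
preranked GSEA with a permutation null, and RaMP-style Jaccard clustering
of enriched metabolite pathways.

A synthetic-data generator produces a complete desk-scale study — a
scale-free gene network with attached metabolites, planted perturbed
modules with known log2 fold changes, and three noisy omics layers over
3 + 3 replicates — so the entire pipeline is testable against ground truth
without any downloads.

## Worked example

The numbered scripts under `analysis/` run the full study. `01` simulates
500 genes + 50 metabolites with three planted 15-node modules
(|log2FC| ≈ 2) profiled at 3-vs-3 replicates; `02`–`05` quantify, test,
enrich, solve the forest and rank subnetworks:

```bash
python analysis/01_simulate_study.py
python analysis/02_differential_abundance.py
python analysis/03_enrichment.py
python analysis/04_network_pcsf.py
python analysis/05_subnetworks.py
```

The last two print:

```
106 prized nodes of 550; forest selects 160 nodes (54 Steiner connectors) in 1 tree(s), objective 25.419
5 subnetworks, 3 pass enrichment FDR < 0.05
  rank 1: subnetwork 2 (26 nodes, density 684, top pathway module_2, FDR 1e-09)
  rank 2: subnetwork 3 (31 nodes, density 646, top pathway module_1, FDR 7.4e-06)
  rank 3: subnetwork 5 (38 nodes, density 496, top pathway module_3, FDR 2.2e-10)
top-3 ranked subnetworks recover 37/45 planted module nodes (recall 0.82)
```

i.e. the three top-ranked subnetworks are exactly the three planted
modules (each labelled by its own pathway), recovering 82% of the planted
nodes. `analysis/06_recovery_benchmark.py` repeats this over ten
independent studies and three effect sizes and writes
`results/recovery_curve.tsv`. All tables land under `results/`.

The same pipeline runs from a plain `key = value` config file on any data
in the documented formats (TSV matrices, GMT genesets, TSV edge lists):

```bash
omicsforest simulate --out-dir study/ --seed 11
omicsforest run-all --config pipeline.cfg
```

A small pre-generated study ships under `data/fixture/` for a quick look
at the file formats.

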