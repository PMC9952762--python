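#!/usr/bin/env python
"""Geneset and metabolite-pathway enrichment on the differential results.

Preranked GSEA of the gene layer (running-sum statistic, permutation
null) against the study's pathway collection, hypergeometric ORA of
differential metabolites, and Jaccard clustering of the enriched
metabolite pathways.  Writes results/gsea_results.tsv,
results/metabolite_ora.tsv and results/pathway_clusters.tsv.
"""

from pathlib import Path

import pandas as pd

from omicsforest import cluster_enriched_pathways, gsea_preranked, parse_gmt, rank_features
from omicsforest.enrichment import GeneSetCollection, ora_table

STUDY = Path("scratch/synthetic_study")
OUT = Path("results")
SEED = 11

stats = pd.read_csv(OUT / "differential_stats.tsv", sep="\t")
collection = parse_gmt(STUDY / "genesets.gmt")

ranked = rank_features(stats[stats["layer"] == "transcript"])
gsea = gsea_preranked(ranked, collection, n_perm=1000, seed=SEED)
pd.DataFrame(
    [{"set_name": r.set_name, "es": r.es, "nes": r.nes, "p_value": r.p_value,
      "fdr": r.fdr, "core_size": len(r.core_members)} for r in gsea]
).to_csv(OUT / "gsea_results.tsv", sep="\t", index=False, float_format="%.10g")
hits = [r for r in gsea if r.fdr < 0.05]
print(f"GSEA: {len(gsea)} sets tested, {len(hits)} at FDR < 0.05:")
for r in sorted(hits, key=lambda r: r.fdr):
    print(f"  {r.set_name}: ES {r.es:+.2f}, FDR {r.fdr:.3g}")

met = stats[stats["layer"] == "metabolite"]
met_universe = set(met["feature_id"])
met_sig = set(met.loc[met["significant"], "feature_id"])
met_sets = [
    (name, set(collection.members(name)) & met_universe)
    for name in sorted(collection.sets)
    if collection.members(name) & met_universe
]
ora = ora_table(met_sig, met_universe, GeneSetCollection({n: ("", frozenset(m)) for n, m in met_sets}))
pd.DataFrame(
    [{"set_name": r.set_name, "overlap": int(r.es), "p_value": r.p_value, "fdr": r.fdr}
     for r in ora]
).to_csv(OUT / "metabolite_ora.tsv", sep="\t", index=False, float_format="%.10g")

enriched = [(r.set_name, set(r.core_members)) for r in ora if r.fdr < 0.05]
clustering = cluster_enriched_pathways(enriched, threshold=0.5)
with open(OUT / "pathway_clusters.tsv", "w") as fh:
    fh.write("set_name\tcluster_id\n")
    for i, cluster in enumerate(clustering.clusters, start=1):
        for name in sorted(cluster):
            fh.write(f"{name}\t{i}\n")
    for name in clustering.unassigned:
        fh.write(f"{name}\tNA\n")
print(f"metabolite ORA: {len(ora)} pathways, {len(enriched)} enriched at FDR < 0.05, "
      f"{len(clustering.clusters)} clusters, {len(clustering.unassigned)} unassigned")
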