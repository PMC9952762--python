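#!/usr/bin/env python
"""Subnetwork decomposition, enrichment and prize-density ranking.

Re-solves the Steiner forest, breaks the induced solution graph into
communities (greedy modularity, resolution 0.5), tests each community's
gene nodes for pathway over-representation, and ranks communities with
best-pathway FDR < 0.05 by prize density.  Scores the result against the
planted ground truth.  Writes results/subnetworks.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from omicsforest import (
    PCSFConfig,
    apply_hub_penalty,
    assign_prizes,
    edge_costs_from_confidence,
    parse_gmt,
    rank_subnetworks,
    read_network,
    solve_pcsf,
    subnetwork_enrichment,
)
from omicsforest.subnetworks import decompose_solution, summary_table

STUDY = Path("scratch/synthetic_study")
OUT = Path("results")

stats = pd.read_csv(OUT / "differential_stats.tsv", sep="\t")
net = read_network(STUDY / "edges.tsv", STUDY / "node_types.tsv")
net = apply_hub_penalty(assign_prizes(net, stats, prize_floor=1.0), mu=0.01)
net = edge_costs_from_confidence(net)
solution = solve_pcsf(net, PCSFConfig(beta=1.0, omega=2.0, mu=0.01))

subs = decompose_solution(solution, net, resolution=0.5)
collection = parse_gmt(STUDY / "genesets.gmt")
universe = net.gene_nodes()
for s in subs:
    subnetwork_enrichment(s, collection, universe)
ranked = rank_subnetworks(subs, fdr_cutoff=0.05)
table = summary_table(subs, net).sort_values("subnetwork_id")
table.to_csv(OUT / "subnetworks.tsv", sep="\t", index=False, float_format="%.10g")

truth = json.loads((STUDY / "truth.json").read_text())
planted = {v for module in truth["planted_modules"] for v in module}
top3 = set()
for s in ranked[:3]:
    top3 |= set(s.node_ids)
recall = len(top3 & planted) / len(planted)

print(f"{len(subs)} subnetworks, {len(ranked)} pass enrichment FDR < 0.05")
for s in ranked:
    top = min(s.enrichment, key=lambda r: r.fdr).set_name if s.enrichment else "NA"
    print(f"  rank {s.rank}: subnetwork {s.subnetwork_id} "
          f"({len(s.node_ids)} nodes, density {s.prize_density:.0f}, "
          f"top pathway {top}, FDR {s.min_fdr:.2g})")
print(f"top-3 ranked subnetworks recover {len(top3 & planted)}/{len(planted)} "
      f"planted module nodes (recall {recall:.2f})")
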