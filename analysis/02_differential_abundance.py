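#!/usr/bin/env python
"""Per-feature differential abundance for the three omics layers.

Transcript TPMs are aggregated to gene level, spectral counts are
NSAF-normalized (and rescaled to parts-per-million for the fold-change
pseudocount), then every layer gets log2FC (KO vs WT), a Welch t-test on
the log2 scale, BH FDR and a significance call.  Writes
results/differential_stats.tsv.
"""

from pathlib import Path

import pandas as pd

from omicsforest import (
    OmicsMatrix,
    differential_stats,
    gene_tpm_from_transcripts,
    nsaf_normalize,
    read_matrix,
)
from omicsforest.diff_abundance import write_stats
from omicsforest.omics_io import read_condition_map, read_tx2gene

STUDY = Path("scratch/synthetic_study")
OUT = Path("results")
OUT.mkdir(exist_ok=True)

conditions = read_condition_map(STUDY / "conditions.tsv")
lengths = dict(
    pd.read_csv(STUDY / "protein_lengths.tsv", sep="\t", header=None,
                names=["id", "len"], dtype={"id": str, "len": int}).itertuples(index=False)
)

gene_tpm = gene_tpm_from_transcripts(
    read_matrix(STUDY / "transcript_tpm.tsv", "transcript", conditions),
    read_tx2gene(STUDY / "tx2gene.tsv"),
)
nsaf = nsaf_normalize(
    read_matrix(STUDY / "protein_spectral_counts.tsv", "protein", conditions,
                protein_lengths=lengths)
)
nsaf_ppm = OmicsMatrix("protein", nsaf.values * 1e6, dict(nsaf.condition),
                       protein_lengths=lengths)
metabolite = read_matrix(STUDY / "metabolite_intensity.tsv", "metabolite", conditions)

tables = {
    "transcript": differential_stats(gene_tpm),
    "protein": differential_stats(nsaf_ppm),
    "metabolite": differential_stats(metabolite),
}
stats = pd.concat(tables.values(), ignore_index=True)
write_stats(stats, OUT / "differential_stats.tsv")

for layer, t in tables.items():
    extreme = t.reindex(t["log2fc"].abs().sort_values(ascending=False).index).head(3)
    calls = int(t["significant"].sum())
    print(f"{layer}: {len(t)} features, {calls} significant; largest effects:")
    for _, row in extreme.iterrows():
        print(f"  {row.feature_id}: log2FC = {row.log2fc:+.2f} (FDR {row.fdr:.3g})")
print(f"wrote {OUT/'differential_stats.tsv'} ({len(stats)} rows)")
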