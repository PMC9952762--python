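#!/usr/bin/env python
"""Planted-module recovery across seeds and signal strengths.

Runs the complete pipeline on ten independently simulated studies at
three planted effect sizes and reports the mean fraction of planted
module nodes recovered by the top-3 ranked subnetworks.  Writes
results/recovery_curve.tsv.
"""

from pathlib import Path

from omicsforest.benchmark import recovery_curve

OUT = Path("results")
SEEDS = [s * 10 for s in range(10)]

table = recovery_curve(SEEDS, signal_means=(2.0, 1.2, 0.5))
table.to_csv(OUT / "recovery_curve.tsv", sep="\t", index=False, float_format="%.6g")

for sm, grp in table.groupby("signal_mean"):
    print(f"signal_mean {sm}: mean recall {grp['recall'].mean():.3f} "
          f"(solution {grp['n_solution_nodes'].mean():.0f} nodes, "
          f"{grp['n_subnetworks'].mean():.1f} subnetworks, "
          f"{grp['n_ranked'].mean():.1f} ranked)")
print(f"wrote {OUT/'recovery_curve.tsv'} ({len(table)} runs)")
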