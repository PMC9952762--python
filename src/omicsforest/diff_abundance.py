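"""Per-feature differential abundance between knockout and wild-type samples.

Produces, for every feature of an omics layer, the knockout-vs-wild-type
log2 fold change on pseudocounted abundances, a Welch unequal-variance
t-test p-value on the log2 scale, Benjamini–Hochberg adjusted FDR, and a
significance call.  The statistic table is a plain DataFrame with columns
``feature_id, layer, log2fc, p_value, fdr, significant`` so externally
computed differential-expression tables (e.g. a negative-binomial fit) can
be imported in its place: the downstream network stages consume only
(log2FC, FDR) pairs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .omics_io import OmicsMatrix

STATS_COLUMNS = ["feature_id", "layer", "log2fc", "p_value", "fdr", "significant"]

__all__ = [
    "compute_log2fc",
    "welch_test",
    "bh_adjust",
    "call_significant",
    "differential_stats",
    "write_stats",
    "read_stats",
]


def _group_values(m: OmicsMatrix) -> tuple[np.ndarray, np.ndarray]:
    ko = m.samples_for("KO")
    wt = m.samples_for("WT")
    if not ko or not wt:
        raise ValueError("both KO and WT samples are required")
    return m.values[ko].to_numpy(), m.values[wt].to_numpy()


def compute_log2fc(m: OmicsMatrix, pseudocount: float = 1.0) -> dict[str, float]:
    """KO-vs-WT log2 fold change per feature.

    log2FC = mean over KO samples of log2(x + pseudocount) minus the same
    mean over WT samples.  Positive values mean higher abundance in the
    knockout.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    ko, wt = _group_values(m)
    lfc = np.log2(ko + pseudocount).mean(axis=1) - np.log2(wt + pseudocount).mean(axis=1)
    return dict(zip(m.feature_ids, lfc.tolist()))


def welch_test(ko: np.ndarray, wt: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance t-test on log2-transformed values.

    Returns (t, two-sided p).  Degenerate inputs follow a documented
    convention: zero variance in both groups gives p = 1 when the means are
    equal and p = 0 when they differ (the data are then noiseless).
    """
    ko = np.asarray(ko, dtype=float)
    wt = np.asarray(wt, dtype=float)
    if ko.size < 2 or wt.size < 2:
        raise ValueError("welch_test needs >= 2 samples per condition")
    if ko.var(ddof=1) == 0.0 and wt.var(ddof=1) == 0.0:
        if ko.mean() == wt.mean():
            return 0.0, 1.0
        return (np.inf if ko.mean() > wt.mean() else -np.inf), 0.0
    t, p = sps.ttest_ind(ko, wt, equal_var=False)
    return float(t), float(p)


def welch_test_feature(m: OmicsMatrix, feature_id: str, pseudocount: float = 1.0) -> float:
    """Two-sided Welch p-value for a single feature of a matrix."""
    ko = m.samples_for("KO")
    wt = m.samples_for("WT")
    row = m.values.loc[feature_id]
    _, p = welch_test(
        np.log2(row[ko].to_numpy(dtype=float) + pseudocount),
        np.log2(row[wt].to_numpy(dtype=float) + pseudocount),
    )
    return p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significant(stats: pd.DataFrame, alpha: float = 0.05, min_abs_lfc: float = 1.0) -> pd.DataFrame:
    """Set the ``significant`` column: fdr < alpha (strict) and |log2fc| >= min_abs_lfc."""
    out = stats.copy()
    out["significant"] = (out["fdr"] < alpha) & (out["log2fc"].abs() >= min_abs_lfc)
    return out


def differential_stats(
    m: OmicsMatrix,
    pseudocount: float = 1.0,
    alpha: float = 0.05,
    min_abs_lfc: float = 1.0,
) -> pd.DataFrame:
    """Full per-feature differential table for one omics layer."""
    lfc = compute_log2fc(m, pseudocount)
    ko, wt = _group_values(m)
    log_ko = np.log2(ko + pseudocount)
    log_wt = np.log2(wt + pseudocount)
    pvals = np.empty(len(m.feature_ids))
    for i in range(len(pvals)):
        _, pvals[i] = welch_test(log_ko[i], log_wt[i])
    stats = pd.DataFrame(
        {
            "feature_id": m.feature_ids,
            "layer": m.layer,
            "log2fc": [lfc[f] for f in m.feature_ids],
            "p_value": pvals,
            "fdr": bh_adjust(pvals),
        }
    )
    return call_significant(stats, alpha=alpha, min_abs_lfc=min_abs_lfc)


def write_stats(stats: pd.DataFrame, path: str | Path) -> None:
    stats.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_stats(path: str | Path) -> pd.DataFrame:
    """Import a differential table (ours or an external tool's) with the standard columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in STATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"differential table {path} lacks columns {missing}")
    return df[STATS_COLUMNS]
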