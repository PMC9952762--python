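"""Readers, writers and quantification normalizations for omics abundance matrices.

One omics layer is a features × samples table of non-negative abundances:
TPM for transcripts, spectral counts for proteins, arbitrary intensity
units for metabolites.  Two defined normalizations live here:

* gene-level TPM aggregation — gene TPM is the sum of its transcripts' TPM;
* NSAF (normalized spectral abundance factor) — length-normalized spectral
  counts rescaled so each sample sums to 1.

The on-disk dialect is strictly tab-separated text with a header row of
sample ids and the feature id in the first column; decimal point '.', no
thousands separators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

LAYERS = ("transcript", "protein", "metabolite")
CONDITIONS = ("WT", "KO")

__all__ = [
    "OmicsMatrix",
    "read_matrix",
    "write_matrix",
    "read_condition_map",
    "read_tx2gene",
    "gene_tpm_from_transcripts",
    "nsaf_normalize",
]


@dataclass
class OmicsMatrix:
    """A single omics layer: non-negative abundance matrix with condition labels.

    Parameters
    ----------
    layer
        One of ``"transcript"``, ``"protein"``, ``"metabolite"``.
    values
        DataFrame of shape (features, samples); index = feature ids,
        columns = sample ids.  All entries finite and >= 0.
    condition
        Mapping sample id -> ``"WT"`` or ``"KO"``; must cover every sample.
    protein_lengths
        Optional mapping feature id -> length in amino acids; required for
        NSAF normalization of the protein layer.
    """

    layer: str
    values: pd.DataFrame
    condition: dict[str, str]
    protein_lengths: dict[str, int] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r} in {self.layer} layer")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValueError("matrix contains non-numeric values")
        if arr.size:
            bad = ~np.isfinite(arr) | (arr < 0)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"negative or non-finite value at feature {idx[i]!r}, "
                    f"sample {self.values.columns[j]!r}"
                )
        missing = [s for s in self.values.columns if s not in self.condition]
        if missing:
            raise ValueError(f"samples missing from condition map: {missing}")
        for s in self.values.columns:
            if self.condition[s] not in CONDITIONS:
                raise ValueError(
                    f"condition for sample {s!r} must be one of {CONDITIONS}, "
                    f"got {self.condition[s]!r}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, condition: str) -> list[str]:
        """Sample ids belonging to one condition, in column order."""
        return [s for s in self.values.columns if self.condition[s] == condition]

    def equals(self, other: "OmicsMatrix") -> bool:
        return (
            self.layer == other.layer
            and self.values.equals(other.values)
            and {s: self.condition[s] for s in self.sample_ids}
            == {s: other.condition.get(s) for s in other.sample_ids}
        )


def read_matrix(
    path: str | Path,
    layer: str,
    condition_map: dict[str, str],
    protein_lengths: dict[str, int] | None = None,
) -> OmicsMatrix:
    """Read a tab-separated abundance table into a validated :class:`OmicsMatrix`.

    The first column holds feature ids, the header row sample ids.  Row and
    column order are preserved.  Errors name the offending feature/sample.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    try:
        values = df.astype(float)
    except ValueError:
        for fid, row in df.iterrows():
            for sid, v in row.items():
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric value {v!r} at feature {fid!r}, sample {sid!r} in {path}"
                    ) from None
        raise
    return OmicsMatrix(
        layer=layer,
        values=values,
        condition=dict(condition_map),
        protein_lengths=protein_lengths,
    )


def write_matrix(m: OmicsMatrix, path: str | Path) -> None:
    """Write the abundance table as TSV, feature ids in the first column."""
    out = m.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.15g")


def read_condition_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample_id, WT|KO) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "condition"], dtype=str)
    return dict(zip(df["sample_id"], df["condition"]))


def read_tx2gene(path: str | Path) -> dict[str, str]:
    """Two-column TSV (transcript_id, gene_id) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["transcript_id", "gene_id"], dtype=str)
    return dict(zip(df["transcript_id"], df["gene_id"]))


def gene_tpm_from_transcripts(m: OmicsMatrix, tx2gene: dict[str, str]) -> OmicsMatrix:
    """Aggregate transcript-level TPM to gene level by summation.

    Gene expression per sample is the sum of that gene's transcript TPMs,
    so per-sample totals are conserved exactly.  Output rows appear in
    order of first occurrence of each gene among the transcripts.
    """
    if m.layer != "transcript":
        raise ValueError(f"expected transcript layer, got {m.layer!r}")
    missing = [t for t in m.feature_ids if t not in tx2gene]
    if missing:
        raise ValueError(f"transcript {missing[0]!r} missing from tx2gene mapping")
    genes = pd.Index([tx2gene[t] for t in m.feature_ids], name="feature_id")
    summed = m.values.groupby(genes, sort=False).sum()
    return OmicsMatrix(layer="transcript", values=summed, condition=dict(m.condition))


def nsaf_normalize(m: OmicsMatrix) -> OmicsMatrix:
    """Normalized spectral abundance factor per sample.

    NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j), so each sample column
    sums to 1.  Requires positive protein lengths for every feature and at
    least one nonzero spectral count per sample.
    """
    if m.layer != "protein":
        raise ValueError(f"NSAF applies to the protein layer, got {m.layer!r}")
    if m.protein_lengths is None:
        raise ValueError("protein_lengths required for NSAF normalization")
    missing = [f for f in m.feature_ids if f not in m.protein_lengths]
    if missing:
        raise ValueError(f"protein length missing for feature {missing[0]!r}")
    lengths = np.array([m.protein_lengths[f] for f in m.feature_ids], dtype=float)
    if (lengths <= 0).any():
        bad = m.feature_ids[int(np.argmax(lengths <= 0))]
        raise ValueError(f"non-positive protein length for feature {bad!r}")
    saf = m.values.to_numpy() / lengths[:, None]
    colsum = saf.sum(axis=0)
    if (colsum == 0).any():
        sample = m.sample_ids[int(np.argmax(colsum == 0))]
        raise ValueError(f"sample {sample!r} has all-zero spectral counts")
    nsaf = pd.DataFrame(saf / colsum, index=m.values.index, columns=m.values.columns)
    return OmicsMatrix(
        layer="protein",
        values=nsaf,
        condition=dict(m.condition),
        protein_lengths=dict(m.protein_lengths),
    )
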