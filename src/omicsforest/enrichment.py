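"""Geneset and metabolite-pathway enrichment.

Three complementary tools:

* preranked GSEA — the weighted Kolmogorov–Smirnov-like running-sum
  statistic over a log2FC-ranked feature list, with a gene-label
  permutation null and BH FDR across sets;
* over-representation analysis (ORA) — the hypergeometric upper tail of
  the overlap between a significant-feature list and a pathway, the
  standard test for metabolite pathway enrichment;
* pathway clustering — grouping enriched pathways whose significant
  members overlap (Jaccard similarity graph, connected components), the
  device used to compress a long enrichment table into a handful of
  interpretable clusters.

GSEA p-values are one-sided conditional on the sign of the observed
enrichment score: for a positive ES the null is the positive-ES
permutations, for a negative ES the negative ones.  This keeps the
p-values uniform under a random-set null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diff_abundance import bh_adjust

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "PathwayClustering",
    "parse_gmt",
    "write_gmt",
    "rank_features",
    "enrichment_score",
    "gsea_preranked",
    "ora_hypergeometric",
    "ora_table",
    "cluster_enriched_pathways",
]


@dataclass
class GeneSetCollection:
    """Named feature sets, typically parsed from a GMT file."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def filtered(self, min_size: int, max_size: int, universe: set[str] | None = None) -> "GeneSetCollection":
        """Restrict to sets whose (optionally universe-intersected) size is within bounds."""
        kept = {}
        for name, (desc, members) in self.sets.items():
            eff = members & universe if universe is not None else members
            if min_size <= len(eff) <= max_size:
                kept[name] = (desc, members)
        return GeneSetCollection(kept)


@dataclass
class EnrichmentResult:
    """One pathway's enrichment outcome (GSEA or ORA)."""

    set_name: str
    statistic_kind: str  # "ES" or "odds"
    es: float  # GSEA enrichment score, or ORA overlap count
    p_value: float
    fdr: float
    core_members: frozenset[str]
    nes: float | None = None


@dataclass
class PathwayClustering:
    clusters: list[frozenset[str]]
    unassigned: list[str]
    similarity_threshold: float


def parse_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name TAB description TAB member...

    Duplicate members within a line are collapsed; a duplicate set name or
    a line with fewer than three fields is an error (with line number).
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def rank_features(stats: pd.DataFrame) -> list[tuple[str, float]]:
    """Rank features by log2FC, descending; ties broken by ascending feature id."""
    if len(stats) == 0:
        raise ValueError("cannot rank an empty feature table")
    if stats["feature_id"].duplicated().any():
        dup = stats.loc[stats["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise ValueError(f"duplicate feature id {dup!r} in ranking input")
    ordered = stats.sort_values(
        ["log2fc", "feature_id"], ascending=[False, True], kind="mergesort"
    )
    return list(zip(ordered["feature_id"], ordered["log2fc"].astype(float)))


def _es_from_indicator(scores: np.ndarray, is_member: np.ndarray, weight_exponent: float) -> tuple[float, int]:
    """Running-sum enrichment score; returns (es, index of the extremum)."""
    n = scores.size
    n_hits = int(is_member.sum())
    weights = np.abs(scores) ** weight_exponent
    hit_total = weights[is_member].sum()
    steps = np.where(
        is_member,
        weights / hit_total if hit_total > 0 else 1.0 / n_hits,
        -1.0 / (n - n_hits),
    )
    running = np.cumsum(steps)
    i_ext = int(np.argmax(np.abs(running)))
    return float(running[i_ext]), i_ext


def enrichment_score(
    ranked: list[tuple[str, float]],
    members: set[str],
    weight_exponent: float = 1.0,
) -> tuple[float, frozenset[str]]:
    """Enrichment score of a feature set against a ranked list, with leading edge.

    The running sum gains |score|^exponent (normalized over hits) at member
    positions and loses 1/(N − N_hits) elsewhere; ES is the extremum of
    largest magnitude, signed.  The leading edge is the members at or
    before the extremum for positive ES, at or after it for negative ES.
    """
    ids = np.array([f for f, _ in ranked])
    scores = np.array([s for _, s in ranked], dtype=float)
    is_member = np.isin(ids, list(members))
    n_hits = int(is_member.sum())
    if n_hits == 0:
        raise ValueError("no set members present in the ranked list")
    if n_hits == ids.size:
        raise ValueError("set covers the entire ranked list")
    es, i_ext = _es_from_indicator(scores, is_member, weight_exponent)
    if es >= 0:
        leading = ids[: i_ext + 1][is_member[: i_ext + 1]]
    else:
        leading = ids[i_ext:][is_member[i_ext:]]
    return es, frozenset(leading.tolist())


def gsea_preranked(
    ranked: list[tuple[str, float]],
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
    weight_exponent: float = 1.0,
) -> list[EnrichmentResult]:
    """Preranked GSEA over a geneset collection with a permutation null.

    The null permutes member positions (scores stay fixed).  For each set,
    p = (1 + #{same-sign null ES with |ES| >= |observed|}) /
    (1 + #{same-sign null ES}); NES = ES / mean |same-sign null ES|; FDR is
    BH across the tested sets.  Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ids = np.array([f for f, _ in ranked])
    scores = np.array([s for _, s in ranked], dtype=float)
    n = ids.size
    universe = set(ids.tolist())

    tested: list[tuple[str, int]] = []
    for name in sorted(collection.sets):
        size = len(collection.members(name) & universe)
        if min_size <= size <= max_size and size < n:
            tested.append((name, size))
    if not tested:
        raise ValueError("no genesets within size bounds overlap the ranked list")

    rng = np.random.default_rng(seed)
    # one shared null per set size: permuting member labels is equivalent to
    # drawing a uniform random position subset of that size
    null_by_size: dict[int, np.ndarray] = {}
    for _, size in tested:
        if size in null_by_size:
            continue
        null_es = np.empty(n_perm)
        indicator = np.zeros(n, dtype=bool)
        for k in range(n_perm):
            pos = rng.choice(n, size=size, replace=False)
            indicator[:] = False
            indicator[pos] = True
            null_es[k], _ = _es_from_indicator(scores, indicator, weight_exponent)
        null_by_size[size] = null_es

    results: list[EnrichmentResult] = []
    pvals = []
    for name, size in tested:
        es, leading = enrichment_score(ranked, set(collection.members(name)), weight_exponent)
        null_es = null_by_size[size]
        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        n_same = int(same_sign.sum())
        n_beyond = int((np.abs(null_es[same_sign]) >= abs(es)).sum())
        p = (1 + n_beyond) / (1 + n_same)
        mean_same = float(np.abs(null_es[same_sign]).mean()) if n_same else np.nan
        nes = es / mean_same if n_same and mean_same > 0 else np.nan
        results.append(
            EnrichmentResult(
                set_name=name,
                statistic_kind="ES",
                es=es,
                nes=nes,
                p_value=p,
                fdr=np.nan,
                core_members=leading,
            )
        )
        pvals.append(p)
    fdrs = bh_adjust(pvals)
    for r, f in zip(results, fdrs):
        r.fdr = float(f)
    return results


def ora_hypergeometric(
    significant: set[str], universe: set[str], members: set[str]
) -> tuple[int, float]:
    """Hypergeometric over-representation test.

    Returns (overlap, P(X >= overlap)) with
    X ~ Hypergeometric(|universe|, |members|, |significant|).
    """
    if not members <= universe:
        raise ValueError("pathway members must be a subset of the universe")
    if not significant <= universe:
        raise ValueError("significant features must be a subset of the universe")
    overlap = len(significant & members)
    # sf(k-1) = P(X >= k)
    p = float(sps.hypergeom.sf(overlap - 1, len(universe), len(members), len(significant)))
    return overlap, min(p, 1.0)


def ora_table(
    significant: set[str],
    universe: set[str],
    collection: GeneSetCollection,
) -> list[EnrichmentResult]:
    """ORA over a collection, restricted to each set's universe members, with BH FDR."""
    names = sorted(collection.sets)
    results = []
    pvals = []
    for name in names:
        members = set(collection.members(name)) & universe
        if not members:
            continue
        overlap, p = ora_hypergeometric(significant, universe, members)
        results.append(
            EnrichmentResult(
                set_name=name,
                statistic_kind="odds",
                es=float(overlap),
                p_value=p,
                fdr=np.nan,
                core_members=frozenset(significant & members),
            )
        )
        pvals.append(p)
    for r, f in zip(results, bh_adjust(pvals)):
        r.fdr = float(f)
    return results


def cluster_enriched_pathways(
    enriched: list[tuple[str, set[str]]], threshold: float = 0.5
) -> PathwayClustering:
    """Group enriched pathways whose significant members overlap.

    Pathways are nodes; an edge joins two pathways when the Jaccard index
    of their significant members reaches ``threshold``.  Connected
    components of size >= 2 are clusters; singletons stay unassigned.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    import networkx as nx

    g = nx.Graph()
    names = [name for name, _ in enriched]
    if len(names) != len(set(names)):
        raise ValueError("duplicate pathway names in clustering input")
    sets = {name: frozenset(s) for name, s in enriched}
    g.add_nodes_from(sorted(names))
    for i, a in enumerate(sorted(names)):
        for b in sorted(names)[i + 1 :]:
            union = sets[a] | sets[b]
            if not union:
                continue
            jac = len(sets[a] & sets[b]) / len(union)
            if jac >= threshold:
                g.add_edge(a, b)
    clusters = []
    unassigned = []
    for comp in nx.connected_components(g):
        if len(comp) >= 2:
            clusters.append(frozenset(comp))
        else:
            unassigned.extend(comp)
    clusters.sort(key=lambda c: sorted(c)[0])
    return PathwayClustering(
        clusters=clusters, unassigned=sorted(unassigned), similarity_threshold=threshold
    )
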