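"""Synthetic multi-omics study generator with planted perturbed modules.

Emulates the structure of a two-condition (wild-type vs knockout)
multi-omics experiment at desk scale, with known ground truth:

* a scale-free gene interaction network (preferential attachment) with
  metabolite nodes attached to a few genes each, edge confidences in
  (0.5, 1);
* a handful of disjoint, connected *planted modules* whose nodes carry a
  strong true log2 fold change (random sign per module); all other
  measured features fluctuate around zero;
* three omics layers over 3-vs-3 replicates by default: transcript-level
  negative-binomial counts scaled to TPM, Poisson spectral counts for a
  protein subset of genes (mirroring the much smaller coverage of a real
  proteome), and log-normal metabolite intensities.

Everything is a deterministic function of the seed.  The generator also
emits a geneset collection in which each planted module is a "true"
pathway alongside size-matched decoy sets, so enrichment and subnetwork
recovery can be scored against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .network import InteractionNetwork, edge_costs_from_confidence
from .omics_io import OmicsMatrix

__all__ = [
    "SyntheticTruth",
    "LayerConfig",
    "simulate_global_network",
    "plant_modules",
    "simulate_omics",
    "module_geneset_collection",
    "write_study",
]


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic study."""

    planted_modules: list[frozenset]
    true_log2fc: dict[str, float]
    module_signal_mean: float
    noise_sd: float
    seed: int

    def module_nodes(self) -> frozenset:
        out: set = set()
        for m in self.planted_modules:
            out |= m
        return frozenset(out)


@dataclass
class LayerConfig:
    """Noise/abundance parameters of the simulated omics layers.

    Transcript counts are negative binomial with dispersion ``nb_dispersion``
    around a log-normal base expression (log-space mean ``base_log_mean``,
    sd ``base_log_sd``); protein spectral counts are Poisson around a
    smaller log-normal base for a random ``protein_fraction`` of genes;
    metabolite log-intensities are normal with sd ``metab_log_sd``.
    """

    nb_dispersion: float = 0.1
    base_log_mean: float = 5.0
    base_log_sd: float = 1.5
    max_transcripts: int = 3
    protein_fraction: float = 0.4
    protein_base_log_mean: float = 3.0
    protein_base_log_sd: float = 1.0
    protein_length_range: tuple[int, int] = (100, 1000)
    metab_base_log_mean: float = 10.0
    metab_base_log_sd: float = 1.0
    metab_log_sd: float = 0.3


def simulate_global_network(
    n_genes: int, n_metabolites: int = 0, attach_m: int = 2, seed: int = 0
) -> InteractionNetwork:
    """Scale-free gene network with attached metabolites.

    Genes grow by preferential attachment from a seed path of ``attach_m``
    nodes (so the gene graph has (n_genes − attach_m)·attach_m + attach_m − 1
    edges and is connected by construction); each metabolite then attaches
    to 1–3 uniformly chosen genes.  Edge confidences are U(0.5, 1).
    """
    if attach_m < 1 or n_genes < attach_m + 1:
        raise ValueError("need n_genes >= attach_m + 1 and attach_m >= 1")
    if n_metabolites < 0:
        raise ValueError("n_metabolites must be >= 0")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    mets = [f"M{i:03d}" for i in range(n_metabolites)]
    net = InteractionNetwork()
    for g in genes:
        net.add_node(g, "gene")
    for m in mets:
        net.add_node(m, "metabolite")

    # degree-proportional sampling via the repeated-endpoints trick
    targets: list[str] = []
    for i in range(1, attach_m):
        net.add_edge(genes[i - 1], genes[i], float(rng.uniform(0.5, 1.0)))
        targets += [genes[i - 1], genes[i]]
    if attach_m == 1:
        targets = [genes[0]]
    for i in range(attach_m, n_genes):
        chosen: set[str] = set()
        while len(chosen) < attach_m:
            chosen.add(targets[int(rng.integers(len(targets)))])
        for t in sorted(chosen):
            net.add_edge(genes[i], t, float(rng.uniform(0.5, 1.0)))
            targets.append(t)
        targets += [genes[i]] * attach_m
    for m in mets:
        k = int(rng.integers(1, 4))
        for g in rng.choice(n_genes, size=min(k, n_genes), replace=False):
            net.add_edge(m, genes[int(g)], float(rng.uniform(0.5, 1.0)))
    return edge_costs_from_confidence(net)


def plant_modules(
    net: InteractionNetwork,
    k: int = 3,
    module_size: int = 15,
    signal_mean: float = 2.0,
    signal_sd: float = 0.4,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> SyntheticTruth:
    """Plant k disjoint connected perturbed modules and draw true log2FCs.

    Modules grow by seeded breadth-first expansion over unused nodes,
    visiting low-degree neighbors first so modules form localized
    peripheral neighborhoods rather than hub-core blobs (a planted module
    should be a distinct network neighborhood, as a perturbed pathway
    would be).  Each module gets a random sign; its nodes get
    log2FC = sign × N(signal_mean, signal_sd), background nodes
    log2FC ~ N(0, noise_sd).
    """
    nodes = net.nodes()
    if k * module_size > len(nodes):
        raise ValueError("modules would exceed the network size")
    rng = np.random.default_rng(seed)
    used: set[str] = set()
    modules: list[frozenset] = []
    for _ in range(k):
        module = None
        for _attempt in range(200):
            start = nodes[int(rng.integers(len(nodes)))]
            if start in used:
                continue
            grown = [start]
            grown_set = {start}
            frontier = [start]
            while frontier and len(grown) < module_size:
                v = frontier.pop(0)
                for u in sorted(net.graph.neighbors(v), key=lambda u: (net.graph.degree(u), u)):
                    if u not in used and u not in grown_set:
                        grown.append(u)
                        grown_set.add(u)
                        frontier.append(u)
                        if len(grown) == module_size:
                            break
            if len(grown) == module_size:
                module = frozenset(grown)
                break
        if module is None:
            raise RuntimeError(f"could not place {k} disjoint connected modules of size {module_size}")
        used |= module
        modules.append(module)

    true_lfc: dict[str, float] = {}
    for module in modules:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        for v in sorted(module):
            true_lfc[v] = float(sign * rng.normal(signal_mean, signal_sd))
    for v in nodes:
        if v not in true_lfc:
            true_lfc[v] = float(rng.normal(0.0, noise_sd))
    return SyntheticTruth(
        planted_modules=modules,
        true_log2fc=true_lfc,
        module_signal_mean=signal_mean,
        noise_sd=noise_sd,
        seed=seed,
    )


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = m + dispersion·m²."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_omics(
    truth: SyntheticTruth,
    net: InteractionNetwork,
    n_reps: int = 3,
    layer_config: LayerConfig | None = None,
    seed: int = 0,
) -> tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix, dict[str, str]]:
    """Simulate (transcript, protein, metabolite) matrices plus tx2gene.

    The knockout condition multiplies each feature's expected abundance by
    2^(true log2FC).  Transcript counts are TPM-scaled per sample (column
    sums 1e6); proteins are raw spectral counts for a random subset of
    genes with random lengths; metabolites are log-normal intensities.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates per condition")
    cfg = layer_config or LayerConfig()
    rng = np.random.default_rng(seed)
    genes = sorted(net.gene_nodes())
    mets = sorted(net.metabolite_nodes())
    samples = [f"WT_{i+1}" for i in range(n_reps)] + [f"KO_{i+1}" for i in range(n_reps)]
    condition = {s: ("KO" if s.startswith("KO") else "WT") for s in samples}
    ko_mask = np.array([condition[s] == "KO" for s in samples], dtype=float)

    # transcript layer: 1..max_transcripts isoforms per gene
    tx_ids: list[str] = []
    tx2gene: dict[str, str] = {}
    tx_base: list[float] = []
    tx_lfc: list[float] = []
    for g in genes:
        base = float(rng.lognormal(cfg.base_log_mean, cfg.base_log_sd))
        n_tx = int(rng.integers(1, cfg.max_transcripts + 1))
        shares = rng.dirichlet(np.ones(n_tx))
        for j in range(n_tx):
            tid = f"{g}.T{j+1}"
            tx_ids.append(tid)
            tx2gene[tid] = g
            tx_base.append(base * float(shares[j]))
            tx_lfc.append(truth.true_log2fc[g])
    mean_tx = np.outer(np.array(tx_base), np.ones(len(samples))) * np.power(
        2.0, np.outer(np.array(tx_lfc), ko_mask)
    )
    counts = _nb_draw(rng, mean_tx, cfg.nb_dispersion).astype(float)
    colsum = counts.sum(axis=0)
    colsum[colsum == 0] = 1.0
    tpm = counts / colsum * 1e6
    transcript = OmicsMatrix(
        layer="transcript",
        values=pd.DataFrame(tpm, index=tx_ids, columns=samples),
        condition=condition,
    )

    # protein layer: Poisson spectral counts for a random gene subset
    n_prot = max(1, int(round(cfg.protein_fraction * len(genes))))
    prot_genes = sorted(rng.choice(genes, size=n_prot, replace=False).tolist())
    prot_base = rng.lognormal(cfg.protein_base_log_mean, cfg.protein_base_log_sd, size=n_prot)
    prot_lfc = np.array([truth.true_log2fc[g] for g in prot_genes])
    mean_prot = np.outer(prot_base, np.ones(len(samples))) * np.power(
        2.0, np.outer(prot_lfc, ko_mask)
    )
    spc = rng.poisson(mean_prot).astype(float)
    lengths = {
        g: int(rng.integers(cfg.protein_length_range[0], cfg.protein_length_range[1] + 1))
        for g in prot_genes
    }
    protein = OmicsMatrix(
        layer="protein",
        values=pd.DataFrame(spc, index=prot_genes, columns=samples),
        condition=condition,
        protein_lengths=lengths,
    )

    # metabolite layer: log-normal intensities for every metabolite node
    met_base = rng.lognormal(cfg.metab_base_log_mean, cfg.metab_base_log_sd, size=len(mets))
    met_lfc = np.array([truth.true_log2fc[m] for m in mets]) if mets else np.zeros(0)
    log_mean = np.log(met_base)[:, None] + np.outer(met_lfc, ko_mask) * np.log(2.0)
    intensities = np.exp(rng.normal(log_mean, cfg.metab_log_sd))
    metabolite = OmicsMatrix(
        layer="metabolite",
        values=pd.DataFrame(intensities, index=mets, columns=samples),
        condition=condition,
    )
    return transcript, protein, metabolite, tx2gene


def module_geneset_collection(
    truth: SyntheticTruth,
    net: InteractionNetwork,
    n_decoys: int = 15,
    seed: int = 0,
) -> GeneSetCollection:
    """Planted modules as 'true' pathways plus size-matched random decoys.

    Module pathways keep their metabolite members (merged pathway
    collections span both molecule types); decoy sets mirror that mix so
    both geneset GSEA and metabolite ORA see true and null pathways.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(net.gene_nodes())
    mets = sorted(net.metabolite_nodes())
    sets: dict[str, tuple[str, frozenset]] = {}
    sizes = []
    for i, module in enumerate(truth.planted_modules, start=1):
        sets[f"module_{i}"] = ("planted perturbed module", frozenset(module))
        sizes.append(len(module & net.gene_nodes()))
    avg = int(round(np.mean(sizes))) if sizes else 10
    n_met = min(3, len(mets))
    for j in range(1, n_decoys + 1):
        decoy = set(rng.choice(genes, size=min(avg, len(genes)), replace=False).tolist())
        if mets:
            decoy |= set(rng.choice(mets, size=n_met, replace=False).tolist())
        sets[f"decoy_{j:02d}"] = ("random decoy set", frozenset(decoy))
    return GeneSetCollection(sets)


def write_study(
    out_dir: str | Path,
    n_genes: int = 500,
    n_metabolites: int = 50,
    attach_m: int = 2,
    k_modules: int = 3,
    module_size: int = 15,
    signal_mean: float = 2.0,
    signal_sd: float = 0.4,
    noise_sd: float = 0.3,
    n_reps: int = 3,
    n_decoys: int = 15,
    seed: int = 0,
    layer_config: LayerConfig | None = None,
) -> dict:
    """Generate a full study to disk in the formats the pipeline consumes.

    Writes the three matrices, tx2gene, condition map, protein lengths,
    edge list + node types, the geneset GMT, and truth.json.  Returns a
    manifest of the written paths plus the in-memory objects.
    """
    from .enrichment import write_gmt
    from .omics_io import write_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = simulate_global_network(n_genes, n_metabolites, attach_m, seed=seed)
    truth = plant_modules(
        net, k=k_modules, module_size=module_size, signal_mean=signal_mean,
        signal_sd=signal_sd, noise_sd=noise_sd, seed=seed + 1,
    )
    transcript, protein, metabolite, tx2gene = simulate_omics(
        truth, net, n_reps=n_reps, layer_config=layer_config, seed=seed + 2
    )
    collection = module_geneset_collection(truth, net, n_decoys=n_decoys, seed=seed + 3)

    write_matrix(transcript, out / "transcript_tpm.tsv")
    write_matrix(protein, out / "protein_spectral_counts.tsv")
    write_matrix(metabolite, out / "metabolite_intensity.tsv")
    with open(out / "tx2gene.tsv", "w") as fh:
        for t in transcript.feature_ids:
            fh.write(f"{t}\t{tx2gene[t]}\n")
    with open(out / "conditions.tsv", "w") as fh:
        for s in transcript.sample_ids:
            fh.write(f"{s}\t{transcript.condition[s]}\n")
    with open(out / "protein_lengths.tsv", "w") as fh:
        for p in protein.feature_ids:
            fh.write(f"{p}\t{protein.protein_lengths[p]}\n")
    with open(out / "edges.tsv", "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u}\t{v}\t{net.graph.edges[u, v]['confidence']:.10g}\n")
    with open(out / "node_types.tsv", "w") as fh:
        for v in net.nodes():
            fh.write(f"{v}\t{net.node_type(v)}\n")
    write_gmt(collection, out / "genesets.gmt")
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "seed": seed,
                "parameters": {
                    "n_genes": n_genes, "n_metabolites": n_metabolites,
                    "attach_m": attach_m, "k_modules": k_modules,
                    "module_size": module_size, "signal_mean": signal_mean,
                    "signal_sd": signal_sd, "noise_sd": noise_sd, "n_reps": n_reps,
                },
                "planted_modules": [sorted(m) for m in truth.planted_modules],
                "true_log2fc": {k: truth.true_log2fc[k] for k in sorted(truth.true_log2fc)},
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return {
        "dir": str(out),
        "network": net,
        "truth": truth,
        "transcript": transcript,
        "protein": protein,
        "metabolite": metabolite,
        "tx2gene": tx2gene,
        "collection": collection,
    }
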