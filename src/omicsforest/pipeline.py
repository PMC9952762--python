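"""End-to-end orchestration: omics tables in, ranked subnetworks out.

Stages (each a pure function of inputs + config + seed):

1. quantification — read the three layers, aggregate transcript TPM to
   gene level, NSAF-normalize spectral counts;
2. differential abundance per layer (protein statistics run on NSAF
   rescaled to parts-per-million so a count-scale pseudocount applies);
3. enrichment — preranked GSEA of the gene layer, metabolite ORA and
   pathway clustering;
4. global network — merge prizes (max |log2FC| across layers) onto the
   typed interaction graph, hub penalty, edge costs;
5. PCSF — solve for the prize-collecting forest;
6. subnetworks — community decomposition, per-subnetwork ORA, prize
   density ranking.

All outputs are TSV/GraphML/JSON with fixed formatting: identical config
and seed reproduce byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import diff_abundance as da
from . import enrichment as enr
from . import network as nw
from . import omics_io as oio
from .pcsf import PCSFConfig, solve_pcsf
from .subnetworks import decompose_solution, rank_subnetworks, subnetwork_enrichment, summary_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "run_pipeline"]

_PATH_KEYS = (
    "transcript_matrix", "protein_matrix", "metabolite_matrix",
    "tx2gene", "conditions", "protein_lengths", "edges", "node_types", "gmt",
)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; see ``load_config`` for the file format."""

    transcript_matrix: str
    protein_matrix: str
    metabolite_matrix: str
    tx2gene: str
    conditions: str
    protein_lengths: str
    edges: str
    node_types: str
    gmt: str
    out_dir: str
    alpha: float = 0.05
    min_abs_lfc: float = 1.0
    pseudocount: float = 1.0
    n_perm: int = 1000
    weight_exponent: float = 1.0
    min_size: int = 5
    max_size: int = 500
    beta: float = 1.0
    omega: float = 2.0
    mu: float = 0.01
    community_algorithm: str = "greedy"
    community_resolution: float = 0.5
    jaccard_threshold: float = 0.5
    fdr_cutoff: float = 0.05
    significant_only_prizes: bool = False
    prize_floor: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        missing = [k for k in _PATH_KEYS if not Path(getattr(self, k)).is_file()]
        if missing:
            raise FileNotFoundError(
                "missing input files: "
                + ", ".join(f"{k}={getattr(self, k)}" for k in missing)
            )


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Parse a plain-text ``key = value`` config file ('#' starts a comment)."""
    raw: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            k, v = (s.strip() for s in line.split("=", 1))
            raw[k] = v
    raw.update({k: str(v) for k, v in overrides.items()})
    kwargs: dict = {}
    for f_name, f_type in RunConfig.__annotations__.items():
        if f_name not in raw:
            continue
        v = raw.pop(f_name)
        if f_type == "float":
            kwargs[f_name] = float(v)
        elif f_type == "int":
            kwargs[f_name] = int(v)
        elif f_type == "bool":
            kwargs[f_name] = v.strip().lower() in ("1", "true", "yes")
        else:
            kwargs[f_name] = v
    if raw:
        raise ValueError(f"unknown config keys: {sorted(raw)}")
    return RunConfig(**kwargs)


def _write_enrichment(results, path: Path) -> None:
    rows = [
        {
            "set_name": r.set_name,
            "statistic_kind": r.statistic_kind,
            "es": r.es,
            "nes": r.nes if r.nes is not None else "NA",
            "p_value": r.p_value,
            "fdr": r.fdr,
            "core_members": ";".join(sorted(r.core_members)),
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; returns (and writes) the JSON run manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": []}

    def stage(name: str, **counts):
        manifest["stages"].append({"name": name, **counts})
        logger.info("stage %s done: %s", name, counts)

    # 1 — quantification
    conditions = oio.read_condition_map(cfg.conditions)
    tx2gene = oio.read_tx2gene(cfg.tx2gene)
    lengths_df = pd.read_csv(cfg.protein_lengths, sep="\t", header=None, names=["id", "len"], dtype={"id": str, "len": int})
    lengths = dict(zip(lengths_df["id"], lengths_df["len"]))
    transcript = oio.read_matrix(cfg.transcript_matrix, "transcript", conditions)
    protein = oio.read_matrix(cfg.protein_matrix, "protein", conditions, protein_lengths=lengths)
    metabolite = oio.read_matrix(cfg.metabolite_matrix, "metabolite", conditions)
    gene_tpm = oio.gene_tpm_from_transcripts(transcript, tx2gene)
    nsaf = oio.nsaf_normalize(protein)
    oio.write_matrix(gene_tpm, out / "gene_tpm.tsv")
    oio.write_matrix(nsaf, out / "protein_nsaf.tsv")
    stage("quantification", transcripts=len(transcript.feature_ids),
          genes=len(gene_tpm.feature_ids), proteins=len(nsaf.feature_ids),
          metabolites=len(metabolite.feature_ids))

    # 2 — differential abundance (protein on NSAF ppm so pseudocount 1 is sane)
    nsaf_ppm = oio.OmicsMatrix("protein", nsaf.values * 1e6, dict(nsaf.condition),
                               protein_lengths=dict(lengths))
    tables = {
        "transcript": da.differential_stats(gene_tpm, cfg.pseudocount, cfg.alpha, cfg.min_abs_lfc),
        "protein": da.differential_stats(nsaf_ppm, cfg.pseudocount, cfg.alpha, cfg.min_abs_lfc),
        "metabolite": da.differential_stats(metabolite, cfg.pseudocount, cfg.alpha, cfg.min_abs_lfc),
    }
    all_stats = pd.concat(tables.values(), ignore_index=True)
    da.write_stats(all_stats, out / "differential_stats.tsv")
    stage("diff_abundance", **{f"n_sig_{k}": int(t["significant"].sum()) for k, t in tables.items()})

    # 3 — enrichment
    collection = enr.parse_gmt(cfg.gmt)
    ranked = enr.rank_features(tables["transcript"])
    gsea = enr.gsea_preranked(
        ranked, collection, n_perm=cfg.n_perm, seed=cfg.seed,
        min_size=cfg.min_size, max_size=cfg.max_size, weight_exponent=cfg.weight_exponent,
    )
    _write_enrichment(gsea, out / "gsea_results.tsv")
    met_stats = tables["metabolite"]
    met_sig = set(met_stats.loc[met_stats["significant"], "feature_id"])
    met_universe = set(met_stats["feature_id"])
    met_sets = [
        (name, set(collection.members(name)) & met_universe)
        for name in sorted(collection.sets)
        if collection.members(name) & met_universe
    ]
    if met_sets:
        met_ora = enr.ora_table(met_sig, met_universe, GeneSetCollectionView(met_sets))
        _write_enrichment(met_ora, out / "metabolite_ora.tsv")
        enriched = [
            (r.set_name, set(r.core_members)) for r in met_ora if r.fdr < cfg.fdr_cutoff
        ]
    else:
        met_ora, enriched = [], []
    clustering = enr.cluster_enriched_pathways(enriched, cfg.jaccard_threshold)
    with open(out / "pathway_clusters.tsv", "w") as fh:
        fh.write("set_name\tcluster_id\n")
        for i, cluster in enumerate(clustering.clusters, start=1):
            for name in sorted(cluster):
                fh.write(f"{name}\t{i}\n")
        for name in clustering.unassigned:
            fh.write(f"{name}\tNA\n")
    stage("enrichment", n_gsea_sets=len(gsea), n_metabolite_sets=len(met_ora),
          n_pathway_clusters=len(clustering.clusters))

    # 4 — global network with prizes
    net = nw.read_network(cfg.edges, cfg.node_types)
    net = nw.assign_prizes(
        net, all_stats,
        significant_only=cfg.significant_only_prizes,
        prize_floor=cfg.prize_floor,
    )
    net = nw.apply_hub_penalty(net, cfg.mu)
    net = nw.edge_costs_from_confidence(net)
    net.write_graphml(out / "global_network.graphml")
    stage("global_network", n_nodes=net.n_nodes, n_edges=net.n_edges,
          n_prized=sum(1 for v in net.graph.nodes if net.prize(v) > 0))

    # 5 — PCSF
    pcfg = PCSFConfig(beta=cfg.beta, omega=cfg.omega, mu=cfg.mu, seed=cfg.seed)
    solution = solve_pcsf(net, pcfg)
    sol_graph = net.induced(solution.selected_nodes)
    for e in sol_graph.edges:
        sol_graph.edges[e]["in_forest"] = frozenset(e) in solution.selected_edges
    for v in sol_graph.nodes:
        sol_graph.nodes[v]["is_steiner"] = v in solution.steiner_nodes
        sol_graph.nodes[v]["measured"] = bool(sol_graph.nodes[v].get("measured", False))
    import networkx as nx
    nx.write_graphml(sol_graph, out / "pcsf_solution.graphml")
    with open(out / "pcsf_forest_edges.tsv", "w") as fh:
        for u, v in solution.edge_list():
            fh.write(f"{u}\t{v}\n")
    with open(out / "pcsf_summary.json", "w") as fh:
        json.dump(
            {
                "n_nodes": solution.n_nodes,
                "n_forest_edges": len(solution.selected_edges),
                "n_solution_edges": sol_graph.number_of_edges(),
                "kappa": solution.kappa,
                "objective": round(solution.objective, 10),
                "n_steiner": len(solution.steiner_nodes),
            },
            fh, indent=1, sort_keys=True,
        )
    stage("pcsf", n_nodes=solution.n_nodes, kappa=solution.kappa,
          n_steiner=len(solution.steiner_nodes))

    # 6 — subnetworks
    subs = decompose_solution(
        solution, net,
        algorithm=cfg.community_algorithm,
        seed=cfg.seed,
        resolution=cfg.community_resolution,
    )
    universe = net.gene_nodes()
    for s in subs:
        subnetwork_enrichment(s, collection, universe)
    ranked_subs = rank_subnetworks(subs, cfg.fdr_cutoff)
    table = summary_table(subs, net).sort_values("subnetwork_id")
    table.to_csv(out / "subnetworks.tsv", sep="\t", index=False, float_format="%.10g")
    stage("subnetworks", n_subnetworks=len(subs), n_ranked=len(ranked_subs))

    manifest["n_stages"] = len(manifest["stages"])
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


class GeneSetCollectionView(enr.GeneSetCollection):
    """A GeneSetCollection built from (name, members) pairs on the fly."""

    def __init__(self, pairs):
        super().__init__({name: ("", frozenset(m)) for name, m in pairs})
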