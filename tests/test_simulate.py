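import json

import networkx as nx
import numpy as np
import pytest

from omicsforest import (
    LayerConfig,
    gene_tpm_from_transcripts,
    compute_log2fc,
    module_geneset_collection,
    plant_modules,
    simulate_global_network,
    simulate_omics,
    write_study,
)


class TestGlobalNetwork:
    def test_gene_edge_count_from_attachment_bookkeeping(self):
        # seed path of m nodes (m-1 edges) + m edges per subsequent node
        net = simulate_global_network(100, 0, attach_m=2, seed=0)
        assert net.n_nodes == 100
        assert net.n_edges == (100 - 2) * 2 + 1

    def test_no_metabolites_gives_pure_gene_network(self):
        net = simulate_global_network(50, 0, seed=1)
        assert net.metabolite_nodes() == set()

    def test_metabolites_attach_to_one_to_three_genes(self):
        net = simulate_global_network(50, 20, seed=2)
        for m in net.metabolite_nodes():
            assert 1 <= net.graph.degree(m) <= 3
            assert all(net.node_type(u) == "gene" for u in net.graph.neighbors(m))

    def test_connected_with_costs_and_confidences(self):
        net = simulate_global_network(80, 10, seed=3)
        assert nx.is_connected(net.graph)
        for u, v, d in net.graph.edges(data=True):
            assert 0.5 <= d["confidence"] <= 1.0
            assert d["cost"] == pytest.approx(1 - d["confidence"])

    def test_same_seed_reproduces_edge_list(self):
        a = simulate_global_network(60, 10, seed=9)
        b = simulate_global_network(60, 10, seed=9)
        assert sorted(map(frozenset, a.graph.edges)) == sorted(map(frozenset, b.graph.edges))

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            simulate_global_network(2, 0, attach_m=2)
        with pytest.raises(ValueError):
            simulate_global_network(10, -1)


class TestPlantModules:
    def test_singleton_module(self):
        net = simulate_global_network(30, 0, seed=4)
        truth = plant_modules(net, k=1, module_size=1, seed=4)
        assert len(truth.planted_modules) == 1
        assert len(truth.planted_modules[0]) == 1

    def test_modules_are_disjoint_and_connected(self):
        net = simulate_global_network(200, 20, seed=5)
        truth = plant_modules(net, k=3, module_size=12, seed=5)
        seen = set()
        for module in truth.planted_modules:
            assert len(module) == 12
            assert not module & seen
            seen |= module
            assert nx.is_connected(net.graph.subgraph(module))

    def test_signal_and_noise_scales(self):
        net = simulate_global_network(400, 40, seed=6)
        truth = plant_modules(net, k=4, module_size=20, signal_mean=2.0,
                              signal_sd=0.4, noise_sd=0.3, seed=6)
        planted = truth.module_nodes()
        in_mod = [abs(truth.true_log2fc[v]) for v in planted]
        background = [abs(truth.true_log2fc[v]) for v in truth.true_log2fc if v not in planted]
        assert np.mean(in_mod) == pytest.approx(2.0, abs=0.25)
        # half-normal mean of N(0, 0.3) is 0.3 * sqrt(2/pi) ~ 0.239
        assert np.mean(background) == pytest.approx(0.3 * np.sqrt(2 / np.pi), abs=0.05)

    def test_oversized_request_rejected(self):
        net = simulate_global_network(20, 0, seed=7)
        with pytest.raises(ValueError):
            plant_modules(net, k=3, module_size=10)


class TestOmicsSimulation:
    def make(self, seed=0, n_reps=3, n_genes=150):
        net = simulate_global_network(n_genes, 15, seed=seed)
        truth = plant_modules(net, k=2, module_size=10, seed=seed + 1)
        layers = simulate_omics(truth, net, n_reps=n_reps, seed=seed + 2)
        return net, truth, layers

    def test_shapes_conditions_and_mapping(self):
        net, truth, (tr, pr, me, tx2gene) = self.make()
        assert set(tx2gene.values()) == net.gene_nodes()
        assert set(tr.feature_ids) == set(tx2gene)
        assert len(pr.feature_ids) == round(0.4 * 150)
        assert set(me.feature_ids) == net.metabolite_nodes()
        for m in (tr, pr, me):
            assert len(m.samples_for("WT")) == 3 and len(m.samples_for("KO")) == 3

    def test_same_seed_bit_identical(self):
        _, _, (a, _, _, _) = self.make(seed=11)
        _, _, (b, _, _, _) = self.make(seed=11)
        assert a.values.equals(b.values)

    # abundant, low-dispersion features: pseudocount and count-noise
    # distortions are negligible there, isolating the estimator itself
    LOW_NOISE = LayerConfig(nb_dispersion=0.01, base_log_mean=7.0, base_log_sd=0.5)

    def test_null_truth_centers_estimates_at_zero(self):
        net = simulate_global_network(200, 0, seed=13)
        truth = plant_modules(net, k=1, module_size=1, signal_mean=0.0,
                              signal_sd=0.0, noise_sd=0.0, seed=13)
        tr, _, _, tx2gene = simulate_omics(truth, net, n_reps=10,
                                           layer_config=self.LOW_NOISE, seed=14)
        gene = gene_tpm_from_transcripts(tr, tx2gene)
        lfc = np.array(list(compute_log2fc(gene).values()))
        assert abs(np.mean(lfc)) < 0.05

    def test_estimation_bias_shrinks_with_replicates(self):
        # one small module keeps the TPM composition shift negligible:
        # a large perturbed expression share offsets every per-sample total
        cfg = LayerConfig(base_log_mean=7.0, base_log_sd=0.5)
        errors = {}
        for n_reps in (3, 10, 50):
            net = simulate_global_network(300, 0, seed=21)
            truth = plant_modules(net, k=1, module_size=6, signal_mean=2.0,
                                  signal_sd=0.0, noise_sd=0.0, seed=22)
            tr, _, _, tx2gene = simulate_omics(truth, net, n_reps=n_reps,
                                               layer_config=cfg, seed=23)
            gene = gene_tpm_from_transcripts(tr, tx2gene)
            lfc = compute_log2fc(gene)
            planted = truth.module_nodes()
            errs = [abs(abs(lfc[v]) - 2.0) for v in planted]
            errors[n_reps] = float(np.mean(errs))
        assert errors[50] < errors[3]
        assert errors[50] < 0.2

    def test_too_few_replicates_rejected(self):
        net = simulate_global_network(20, 0, seed=1)
        truth = plant_modules(net, k=1, module_size=2, seed=1)
        with pytest.raises(ValueError):
            simulate_omics(truth, net, n_reps=1)


class TestStudyExport:
    def test_written_study_is_complete_and_recorded(self, tmp_path):
        out = write_study(tmp_path / "study", n_genes=60, n_metabolites=8,
                          k_modules=2, module_size=6, seed=3)
        for name in (
            "transcript_tpm.tsv", "protein_spectral_counts.tsv",
            "metabolite_intensity.tsv", "tx2gene.tsv", "conditions.tsv",
            "protein_lengths.tsv", "edges.tsv", "node_types.tsv",
            "genesets.gmt", "truth.json",
        ):
            assert (tmp_path / "study" / name).is_file()
        truth = json.loads((tmp_path / "study" / "truth.json").read_text())
        assert len(truth["planted_modules"]) == 2
        assert truth["parameters"]["n_genes"] == 60
        coll = out["collection"]
        assert "module_1" in coll.sets and "module_2" in coll.sets

    def test_module_genesets_include_decoys_of_matched_size(self):
        net = simulate_global_network(100, 10, seed=4)
        truth = plant_modules(net, k=2, module_size=8, seed=5)
        coll = module_geneset_collection(truth, net, n_decoys=5, seed=6)
        decoys = [n for n in coll.sets if n.startswith("decoy")]
        assert len(decoys) == 5
        gene_sizes = {len(coll.members(d) & net.gene_nodes()) for d in decoys}
        module_gene_sizes = [
            len(m & net.gene_nodes()) for m in truth.planted_modules
        ]
        assert gene_sizes == {int(round(np.mean(module_gene_sizes)))}
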