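import itertools
import math

import numpy as np
import pandas as pd
import pytest

from omicsforest import (
    GeneSetCollection,
    cluster_enriched_pathways,
    enrichment_score,
    gsea_preranked,
    ora_hypergeometric,
    parse_gmt,
    rank_features,
)


def running_sum_oracle(ranked, members, exponent):
    """Single-pass brute-force running sum, independent of the implementation."""
    weights = [abs(s) ** exponent for _, s in ranked]
    hit_total = sum(w for (f, _), w in zip(ranked, weights) if f in members)
    n_hits = sum(1 for f, _ in ranked if f in members)
    miss_step = 1.0 / (len(ranked) - n_hits)
    best, cum = 0.0, 0.0
    for (f, _), w in zip(ranked, weights):
        cum += w / hit_total if f in members else -miss_step
        if abs(cum) > abs(best):
            best = cum
    return best


def hypergeom_tail_oracle(N, K, n, k):
    """P(X >= k) summed from binomial coefficients."""
    total = 0.0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
    return total


def stats_frame(lfc):
    return pd.DataFrame(
        {"feature_id": list(lfc), "layer": "transcript", "log2fc": list(lfc.values()),
         "p_value": 0.5, "fdr": 0.5, "significant": False}
    )


class TestGMT:
    def test_members_parsed(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("P1\tdesc\tG1\tG2\nP2\tother\tG3\tG4\tG5\n")
        coll = parse_gmt(p)
        assert coll.members("P1") == {"G1", "G2"}
        assert len(coll.members("P2")) == 3

    def test_duplicate_members_collapsed(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("P1\tdesc\tG1\tG1\n")
        assert parse_gmt(p).members("P1") == {"G1"}

    def test_short_line_and_duplicate_name_rejected(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("P1\tdesc-only\n")
        with pytest.raises(ValueError, match=":1"):
            parse_gmt(p)
        p.write_text("P1\td\tG1\nP1\td\tG2\n")
        with pytest.raises(ValueError, match="duplicate"):
            parse_gmt(p)


class TestRanking:
    def test_descending_by_fold_change(self):
        ranked = rank_features(stats_frame({"A": 2.0, "B": -1.0, "C": 3.0}))
        assert [f for f, _ in ranked] == ["C", "A", "B"]

    def test_ties_break_by_feature_id(self):
        ranked = rank_features(stats_frame({"B": 1.0, "A": 1.0}))
        assert [f for f, _ in ranked] == ["A", "B"]

    def test_empty_and_duplicate_inputs_rejected(self):
        with pytest.raises(ValueError):
            rank_features(stats_frame({}))
        frame = pd.concat([stats_frame({"A": 1.0})] * 2, ignore_index=True)
        with pytest.raises(ValueError, match="A"):
            rank_features(frame)


class TestEnrichmentScore:
    def test_member_at_top_gives_plus_one(self):
        ranked = [("A", 4.0), ("B", 3.0), ("C", 2.0), ("D", 1.0)]
        es, leading = enrichment_score(ranked, {"A"})
        assert es == pytest.approx(1.0)
        assert leading == {"A"}

    def test_member_at_bottom_gives_minus_one(self):
        ranked = [("A", 4.0), ("B", 3.0), ("C", 2.0), ("D", 1.0)]
        es, leading = enrichment_score(ranked, {"D"})
        assert es == pytest.approx(-1.0)
        assert leading == {"D"}

    def test_degenerate_sets_rejected(self):
        ranked = [("A", 2.0), ("B", 1.0)]
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"A", "B"})
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"Z"})

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(19)
        for _ in range(500):
            n = int(rng.integers(5, 60))
            ids = [f"F{i:02d}" for i in range(n)]
            scores = rng.normal(0, 2, n)
            order = np.argsort(-scores)
            ranked = [(ids[i], float(scores[i])) for i in order]
            k = int(rng.integers(1, n))
            members = set(rng.choice(ids, size=k, replace=False).tolist())
            exponent = float(rng.choice([0.0, 0.5, 1.0, 2.0]))
            es, _ = enrichment_score(ranked, members, exponent)
            assert es == pytest.approx(running_sum_oracle(ranked, members, exponent), abs=1e-12)


class TestGseaPreranked:
    def exhaustive_singleton_p(self, ranked):
        """Exhaustive member-placement null with the sign-conditional rule."""
        es_by_pos = []
        for f, _ in ranked:
            es, _ = enrichment_score(ranked, {f})
            es_by_pos.append(es)
        obs = es_by_pos[0]
        same = [e for e in es_by_pos if (e >= 0) == (obs >= 0)]
        beyond = sum(1 for e in same if abs(e) >= abs(obs))
        return (1 + beyond) / (1 + len(same))

    def test_singleton_top_set_matches_exhaustive_null(self):
        ranked = [("A", 4.0), ("B", 3.0), ("C", 2.0), ("D", 1.0)]
        coll = GeneSetCollection({"top": ("", frozenset({"A"}))})
        res = gsea_preranked(ranked, coll, n_perm=4000, seed=1, min_size=1, max_size=10)[0]
        assert res.es == pytest.approx(1.0)
        # null has two positive placements (ES +1 and +2/3); only +1 is as
        # extreme, so the add-one-smoothed exhaustive p is (1+1)/(1+2)
        assert self.exhaustive_singleton_p(ranked) == pytest.approx(2 / 3)
        # the sampled permutation null hits each placement ~n_perm/4 times,
        # so its p converges to the unsmoothed placement ratio 1/2
        assert res.p_value == pytest.approx(0.5, abs=0.03)

    def test_same_seed_reproduces_output(self):
        rng = np.random.default_rng(4)
        ids = [f"F{i}" for i in range(40)]
        scores = sorted(rng.normal(0, 1, 40).tolist(), reverse=True)
        ranked = list(zip(ids, scores))
        coll = GeneSetCollection(
            {f"S{j}": ("", frozenset(rng.choice(ids, 8, replace=False).tolist())) for j in range(5)}
        )
        a = gsea_preranked(ranked, coll, n_perm=200, seed=9)
        b = gsea_preranked(ranked, coll, n_perm=200, seed=9)
        assert [(r.set_name, r.es, r.p_value, r.fdr) for r in a] == [
            (r.set_name, r.es, r.p_value, r.fdr) for r in b
        ]

    def test_null_sets_produce_uniform_p_values(self):
        rng = np.random.default_rng(23)
        ids = [f"F{i:03d}" for i in range(150)]
        scores = sorted(rng.normal(0, 1, 150).tolist(), reverse=True)
        ranked = list(zip(ids, scores))
        sets = {
            f"S{j:03d}": ("", frozenset(rng.choice(ids, int(rng.integers(5, 30)), replace=False).tolist()))
            for j in range(400)
        }
        res = gsea_preranked(ranked, GeneSetCollection(sets), n_perm=1000, seed=3)
        frac = np.mean([r.p_value < 0.05 for r in res])
        assert 0.02 <= frac <= 0.08

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            gsea_preranked([("A", 1.0)], GeneSetCollection({}), n_perm=10)


class TestORA:
    def test_printed_worked_case(self):
        universe = {f"U{i}" for i in range(10)}
        members = set(sorted(universe)[:5])
        significant = set(sorted(members)[:4])
        overlap, p = ora_hypergeometric(significant, universe, members)
        assert overlap == 4
        assert p == pytest.approx(5 / 210, abs=1e-12)

    def test_empty_significant_gives_p_one(self):
        universe = {"a", "b", "c"}
        assert ora_hypergeometric(set(), universe, {"a"}) == (0, 1.0)

    def test_significant_equals_universe_gives_p_one(self):
        universe = {"a", "b", "c", "d"}
        overlap, p = ora_hypergeometric(universe, universe, {"a", "b"})
        assert overlap == 2
        assert p == pytest.approx(1.0)

    def test_subset_preconditions_enforced(self):
        with pytest.raises(ValueError):
            ora_hypergeometric({"x"}, {"a"}, {"a"})
        with pytest.raises(ValueError):
            ora_hypergeometric({"a"}, {"a"}, {"z"})

    def test_matches_combinatorial_sum_exhaustively(self):
        for N in (4, 7, 10, 12):
            universe = {f"u{i}" for i in range(N)}
            ordered = sorted(universe)
            for K, n in itertools.product(range(1, N + 1), range(0, N + 1)):
                members = set(ordered[:K])
                significant = set(ordered[N - n:])
                overlap, p = ora_hypergeometric(significant, universe, members)
                assert p == pytest.approx(
                    hypergeom_tail_oracle(N, K, n, overlap), abs=1e-12
                )


class TestPathwayClustering:
    def test_identical_members_form_a_cluster(self):
        out = cluster_enriched_pathways([("P1", {"a", "b"}), ("P2", {"a", "b"})], 0.5)
        assert out.clusters == [frozenset({"P1", "P2"})]
        assert out.unassigned == []

    def test_disjoint_members_all_unassigned(self):
        out = cluster_enriched_pathways([("P1", {"a"}), ("P2", {"b"}), ("P3", {"c"})], 0.5)
        assert out.clusters == []
        assert out.unassigned == ["P1", "P2", "P3"]

    def test_transitive_chain_merges_into_one_cluster(self):
        # A~B and B~C above threshold, A~C below: one connected component
        a = set(range(10))
        b = set(range(2, 12))          # Jaccard(a,b) = 8/12 = 0.67
        c = set(range(4, 14))          # Jaccard(b,c) = 0.67, Jaccard(a,c) = 6/14 = 0.43
        out = cluster_enriched_pathways([("A", a), ("B", b), ("C", c)], 0.5)
        assert out.clusters == [frozenset({"A", "B", "C"})]

    def test_invariant_to_input_order(self):
        pathways = [("A", {1, 2, 3}), ("B", {2, 3, 4}), ("C", {9}), ("D", {1, 2, 3, 4})]
        fwd = cluster_enriched_pathways(pathways, 0.5)
        rev = cluster_enriched_pathways(pathways[::-1], 0.5)
        assert fwd.clusters == rev.clusters
        assert fwd.unassigned == rev.unassigned

    def test_empty_input_gives_empty_clustering(self):
        out = cluster_enriched_pathways([], 0.5)
        assert out.clusters == [] and out.unassigned == []
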