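import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ranklap.errors import ConfigError, InputError
from ranklap import network_enrichment as ne
from ranklap.evaluation import es_prefix_oracle
from ranklap import rank_overlap as ro


def star_network():
    # hub h connected to three reference genes with weights 1, 2, 3
    return ne.InteractionNetwork(
        [("hub", "r1", 1.0), ("hub", "r2", 2.0), ("hub", "r3", 3.0),
         ("lonely", "r1", 0.0)]
    )


class TestInteractionNetwork:
    def test_rejects_self_loops_and_bad_weights(self):
        with pytest.raises(InputError):
            ne.InteractionNetwork([("a", "a", 1.0)])
        with pytest.raises(InputError):
            ne.InteractionNetwork([("a", "b", -1.0)])

    def test_edge_list_round_trip(self, tmp_path):
        net = star_network()
        path = tmp_path / "net.tsv"
        ne.write_network(net, path)
        back = ne.read_network(path)
        assert back.nodes == net.nodes
        assert (back.adjacency != net.adjacency).nnz == 0


class TestScoreAgainstReference:
    def test_star_network_hub_sums_weights(self):
        scored = ne.score_against_reference(star_network(), ["r1", "r2", "r3"])
        by_gene = dict(zip(scored.gene_ids, scored.scores))
        assert by_gene["hub"] == 6.0
        # reference genes are pinned to the max non-reference score
        assert by_gene["r1"] == by_gene["r2"] == by_gene["r3"] == 6.0

    def test_unconnected_gene_scores_zero_and_ranks_last(self):
        scored = ne.score_against_reference(star_network(), ["r2", "r3"])
        by_gene = dict(zip(scored.gene_ids, scored.scores))
        assert by_gene["lonely"] == 0.0
        assert set(scored.df.tail(2)["gene_id"]) == {"lonely", "r1"}  # both score 0

    def test_no_reference_in_network_is_error(self):
        with pytest.raises(InputError):
            ne.score_against_reference(star_network(), ["absent"])

    def test_matches_adjacency_sum_oracle(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i:03d}" for i in range(60)]
        edges = []
        for i in range(60):
            for j in range(i + 1, 60):
                if rng.random() < 0.15:
                    edges.append((genes[i], genes[j], float(rng.random())))
        net = ne.InteractionNetwork(edges)
        ref = list(rng.choice(genes, 12, replace=False))
        scored = ne.score_against_reference(net, ref)
        by_gene = dict(zip(scored.gene_ids, scored.scores))
        expected = {g: 0.0 for g in net.nodes}
        for a, b, w in edges:
            if b in ref:
                expected[a] += w
            if a in ref:
                expected[b] += w
        max_non_ref = max(v for g, v in expected.items() if g not in ref)
        for g in net.nodes:
            want = max_non_ref if g in ref else expected[g]
            assert by_gene[g] == pytest.approx(want)

    def test_adding_reference_edge_never_decreases_score(self):
        edges = [("a", "r1", 1.0), ("b", "r1", 2.0)]
        net1 = ne.InteractionNetwork(edges)
        net2 = ne.InteractionNetwork(edges + [("a", "r1", 0.5)])  # duplicate sums
        sc1 = ne.score_against_reference(net1, ["r1"])
        sc2 = ne.score_against_reference(net2, ["r1"])
        s1 = dict(zip(sc1.gene_ids, sc1.scores))
        s2 = dict(zip(sc2.gene_ids, sc2.scores))
        assert s2["a"] >= s1["a"]


class TestExpandQuery:
    def test_chain_expansion_is_hand_traceable(self):
        net = ne.InteractionNetwork(
            [("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0)]
        )
        sets = ne.expand_query(net, ["a"], sizes=[2, 3])
        assert sets[2] == {"a", "b"}
        assert sets[3] == {"a", "b", "c"}

    def test_seed_at_or_beyond_size_snapshots_identical(self):
        net = ne.InteractionNetwork([("a", "b", 1.0), ("b", "c", 1.0)])
        sets = ne.expand_query(net, ["a", "b", "c"], sizes=[2])
        assert sets[2] == {"a", "b", "c"}

    def test_nestedness(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i:03d}" for i in range(80)]
        edges = [
            (genes[i], genes[j], float(rng.random()))
            for i in range(80) for j in range(i + 1, 80) if rng.random() < 0.1
        ]
        net = ne.InteractionNetwork(edges)
        sets = ne.expand_query(net, genes[:5], sizes=[10, 20, 40])
        assert sets[10] < sets[20] < sets[40]

    def test_sizes_beyond_network_truncated_with_warning(self, caplog):
        net = ne.InteractionNetwork([("a", "b", 1.0), ("b", "c", 1.0)])
        with caplog.at_level("WARNING"):
            sets = ne.expand_query(net, ["a"], sizes=[2, 50])
        assert list(sets) == [2]
        assert "truncating" in caplog.text


class TestGseaPreranked:
    @staticmethod
    def ranked_list(n=10, seed=0):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.random(n))[::-1] + 0.1
        genes = np.array([f"g{i:02d}" for i in range(n)])
        return ne.ScoredGeneList(df=pd.DataFrame({"gene_id": genes, "score": scores}))

    def test_top_genes_es_matches_prefix_oracle(self):
        ranked = self.ranked_list()
        res = ne.gsea_preranked(ranked, ranked.gene_ids[:3], n_perm=10, seed=0)
        mask = np.zeros(10, dtype=bool)
        mask[:3] = True
        assert res.es == pytest.approx(es_prefix_oracle(ranked.scores, mask), abs=1e-12)
        assert res.es > 0

    def test_full_set_rejected(self):
        ranked = self.ranked_list()
        with pytest.raises(InputError):
            ne.gsea_preranked(ranked, ranked.gene_ids, n_perm=10, seed=0)

    def test_disjoint_set_rejected(self):
        ranked = self.ranked_list()
        with pytest.raises(InputError):
            ne.gsea_preranked(ranked, ["absent"], n_perm=10, seed=0)

    def test_es_bounded_and_nes_sign_matches(self):
        rng = np.random.default_rng(2)
        ranked = self.ranked_list(50, seed=2)
        for _ in range(20):
            size = int(rng.integers(1, 49))
            gene_set = rng.choice(ranked.gene_ids, size, replace=False)
            res = ne.gsea_preranked(ranked, gene_set, n_perm=50, seed=3)
            assert -1 <= res.es <= 1
            if np.isfinite(res.nes) and res.nes != 0:
                assert np.sign(res.nes) == np.sign(res.es)

    def test_reproducible_under_seed(self):
        ranked = self.ranked_list(30, seed=4)
        a = ne.gsea_preranked(ranked, ranked.gene_ids[5:15], n_perm=100, seed=9)
        b = ne.gsea_preranked(ranked, ranked.gene_ids[5:15], n_perm=100, seed=9)
        assert (a.es, a.nes, a.pvalue) == (b.es, b.nes, b.pvalue)

    def test_nominal_p_uniform_under_null(self):
        # continuously scored list + random sets: the observed set is
        # exchangeable with its label permutations, so p ~ U(0,1)
        rng0 = np.random.default_rng(0)
        genes = np.array([f"g{i:03d}" for i in range(60)])
        ranked = ne.ScoredGeneList(
            df=pd.DataFrame(
                {"gene_id": genes, "score": np.sort(rng0.random(60))[::-1]}
            )
        )
        rng = np.random.default_rng(5)
        pvals = []
        for k in range(200):
            gene_set = rng.choice(genes, 10, replace=False)
            res = ne.gsea_preranked(ranked, gene_set, n_perm=199, seed=1000 + k)
            pvals.append(res.pvalue)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestOverlapProfile:
    @staticmethod
    def community_network(seed=0, n=120, n_comm=2, p_in=0.3, p_out=0.02):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:03d}" for i in range(n)]
        comm = {g: i % n_comm for i, g in enumerate(genes)}
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                p = p_in if comm[genes[i]] == comm[genes[j]] else p_out
                if rng.random() < p:
                    edges.append((genes[i], genes[j], float(rng.random()) + 0.1))
        return ne.InteractionNetwork(edges), comm

    def test_self_comparison_attains_minimal_p(self):
        net, _ = self.community_network()
        seed_genes = net.nodes[:20]
        prof = ne.overlap_profile(
            net, seed_genes, seed_genes, sizes=[20, 40], n_perm=99, seed=0
        )
        assert (prof.df["pvalue"] == 1 / 100).all()
        assert prof.df["es"].iloc[0] > 0

    def test_profile_has_bh_adjustment_and_flags(self):
        net, comm = self.community_network(seed=1)
        c0 = sorted(g for g, c in comm.items() if c == 0)
        prof = ne.overlap_profile(
            net, c0[:20], c0[20:40], sizes=[20, 40, 55], n_perm=99, seed=1
        )
        assert {"size", "es", "nes", "pvalue", "p_adjusted", "significant"} <= set(
            prof.df.columns
        )
        assert (prof.df["p_adjusted"] >= prof.df["pvalue"] - 1e-12).all()

    def test_region_comparison_same_machinery(self):
        net, comm = self.community_network(seed=2)
        c0 = sorted(g for g, c in comm.items() if c == 0)
        prof = ne.region_comparison(net, c0[:15], c0[15:30], sizes=[20, 40],
                                    n_perm=49, seed=2)
        assert prof.reference_label == "region"
        assert len(prof.df) == 2
        with pytest.raises(InputError):
            ne.region_comparison(net, [], c0[:5], sizes=[10])

    def test_region_disjoint_from_network_is_error(self):
        net, _ = self.community_network(seed=3)
        with pytest.raises(InputError):
            ne.region_comparison(net, ["nope1", "nope2"], net.nodes[:5], sizes=[10])


class TestRegionSnpFraction:
    @staticmethod
    def result_with_cells(bins_a, bins_b, chrom, pos, cells):
        n = len(bins_a)
        pairs = ro.PairedRanks(
            rank_a=np.arange(1, n + 1), rank_b=np.arange(1, n + 1),
            bin_a=np.asarray(bins_a), bin_b=np.asarray(bins_b),
            n_snps=n, n_bins=int(max(np.max(bins_a), np.max(bins_b))),
            snp_id=np.array([f"rs{i}" for i in range(n)]),
            chrom=np.asarray(chrom), pos=np.asarray(pos),
        )
        sig = pd.DataFrame(
            [{"bin_a": a, "bin_b": b, "z": 9.0, "p_bonferroni": 1e-9} for a, b in cells]
        )
        result = ro.CrossTableResult(
            counts=np.zeros((2, 2)), mean_count=0, sd_count=1,
            zscores=np.zeros((2, 2)),
            significant_cells=sig if cells else pd.DataFrame(
                columns=["bin_a", "bin_b", "z", "p_bonferroni"]
            ),
        )
        return result, pairs

    def test_zero_and_full_fraction(self):
        result, pairs = self.result_with_cells(
            [2, 2, 1], [2, 2, 1], ["22", "1", "22"], [100, 100, 100], [(2, 2)]
        )
        frac = ne.region_snp_fraction(result, pairs, ("22", 50, 200))
        assert frac == pytest.approx(50.0)
        frac = ne.region_snp_fraction(result, pairs, ("7", 1, 10))
        assert frac == 0.0
        result2, pairs2 = self.result_with_cells(
            [2], [2], ["22"], [100], [(2, 2)]
        )
        assert ne.region_snp_fraction(result2, pairs2, ("22", 1, 1000)) == 100.0

    def test_undefined_without_significant_cells(self):
        result, pairs = self.result_with_cells([1], [1], ["22"], [100], [])
        assert ne.region_snp_fraction(result, pairs, ("22", 1, 1000)) is None

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(6)
        n = 500
        bins_a = rng.integers(1, 5, n)
        bins_b = rng.integers(1, 5, n)
        chrom = rng.choice(["21", "22"], n)
        pos = rng.integers(1, 10_000, n)
        cells = [(4, 4), (3, 4)]
        result, pairs = self.result_with_cells(bins_a, bins_b, chrom, pos, cells)
        got = ne.region_snp_fraction(result, pairs, ("22", 2000, 8000))
        in_cell = [(a, b) in set(cells) for a, b in zip(bins_a, bins_b)]
        in_region = (chrom == "22") & (pos >= 2000) & (pos <= 8000)
        expected = 100 * sum(c and r for c, r in zip(in_cell, in_region)) / sum(in_cell)
        assert got == pytest.approx(expected)
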