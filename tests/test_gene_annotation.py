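import numpy as np
import pandas as pd
import pytest

from ranklap.errors import InputError
from ranklap import gene_annotation as ga

from conftest import make_summary


def simple_model():
    """Two genes on chr1: plus-strand with two exons, minus-strand intronless."""
    genes = pd.DataFrame(
        {
            "gene_id": ["GENE1", "GENE2"],
            "gene_symbol": ["GENE1", "GENE2"],
            "chrom": ["1", "1"],
            "start0": [1000, 20000],
            "end0": [5000, 24000],
            "strand": ["+", "-"],
        }
    )
    exons = {
        "GENE1": [(1000, 2000), (4000, 5000)],
        "GENE2": [(20000, 24000)],
    }
    return ga.GeneModel(genes=genes, exons=exons)


def annotate_one(chrom, pos, model=None, window=1000):
    s = make_summary("s", ["rs1"], [chrom], [pos], [0.5])
    return ga.annotate(s, model or simple_model(), window=window).df.iloc[0]


class TestAnnotate:
    def test_exonic_containment(self):
        row = annotate_one("1", 1500)
        assert (row["category"], row["gene_id"]) == ("exonic", "GENE1")

    def test_intronic_between_exons(self):
        row = annotate_one("1", 3000)
        assert (row["category"], row["gene_id"]) == ("intronic", "GENE1")

    def test_downstream_window_boundary_plus_strand(self):
        # GENE1 is +strand ending at 0-based 5000 (last base 1-based 5000)
        row = annotate_one("1", 5500)
        assert (row["category"], row["gene_id"]) == ("downstream", "GENE1")
        assert row["distance"] == 500
        assert annotate_one("1", 6000)["category"] == "downstream"
        assert annotate_one("1", 6001)["category"] == "intergenic"

    def test_strand_flips_upstream_downstream(self):
        # beyond the right end of the -strand gene lies its 5' side
        row = annotate_one("1", 24500)
        assert (row["category"], row["gene_id"]) == ("upstream", "GENE2")
        row = annotate_one("1", 19500)
        assert (row["category"], row["gene_id"]) == ("downstream", "GENE2")

    def test_off_chromosome_is_intergenic(self):
        row = annotate_one("2", 1500)
        assert row["category"] == "intergenic"
        assert row["gene_id"] == ""

    def test_matches_brute_force_interval_scan(self):
        rng = np.random.default_rng(0)
        n_genes, n_snps, window = 25, 400, 500
        starts = np.sort(rng.choice(np.arange(0, 200_000, 100), n_genes, replace=False))
        genes = pd.DataFrame(
            {
                "gene_id": [f"G{i:03d}" for i in range(n_genes)],
                "gene_symbol": [f"G{i:03d}" for i in range(n_genes)],
                "chrom": "1",
                "start0": starts,
                "end0": starts + rng.integers(200, 3000, n_genes),
                "strand": rng.choice(["+", "-"], n_genes),
            }
        )
        exons = {
            r.gene_id: [(r.start0, r.start0 + (r.end0 - r.start0) // 3),
                        (r.end0 - (r.end0 - r.start0) // 3, r.end0)]
            for r in genes.itertuples(index=False)
        }
        model = ga.GeneModel(genes=genes, exons=exons)
        pos = rng.integers(1, 210_000, n_snps)
        summary = make_summary("s", [f"rs{i}" for i in range(n_snps)],
                               ["1"] * n_snps, pos, rng.random(n_snps))
        got = ga.annotate(summary, model, window=window).df

        prio = {"exonic": 0, "intronic": 1, "upstream": 2, "downstream": 2}
        for i in range(n_snps):
            p0 = pos[i] - 1
            best = None
            for r in genes.itertuples(index=False):
                if r.start0 <= p0 < r.end0:
                    cat = ("exonic" if any(s <= p0 < e for s, e in exons[r.gene_id])
                           else "intronic")
                elif p0 < r.start0 and r.start0 - p0 <= window:
                    cat = "upstream" if r.strand == "+" else "downstream"
                elif p0 >= r.end0 and p0 - r.end0 + 1 <= window:
                    cat = "downstream" if r.strand == "+" else "upstream"
                else:
                    continue
                key = (prio[cat], abs((r.start0 + r.end0) / 2 - p0), r.gene_id)
                if best is None or key < best[0]:
                    best = (key, cat, r.gene_id)
            expected = ("intergenic", "") if best is None else (best[1], best[2])
            assert (got.loc[i, "category"], got.loc[i, "gene_id"]) == expected

    def test_window_shrink_never_changes_genic_calls(self):
        rng = np.random.default_rng(1)
        model = simple_model()
        pos = rng.integers(1, 30_000, 300)
        s = make_summary("s", [f"rs{i}" for i in range(300)], ["1"] * 300, pos,
                         rng.random(300))
        wide = ga.annotate(s, model, window=2000).df
        narrow = ga.annotate(s, model, window=200).df
        genic = wide["category"].isin(["exonic", "intronic"])
        pd.testing.assert_frame_equal(wide[genic], narrow[genic])
        # shrinking can only move proximal calls to intergenic, never create them
        proximal_narrow = narrow["category"].isin(["upstream", "downstream"])
        proximal_wide = wide["category"].isin(["upstream", "downstream"])
        assert not (proximal_narrow & ~proximal_wide).any()

    def test_coarse_mode_without_exons_is_exonic(self, caplog):
        model = ga.GeneModel(genes=simple_model().genes, exons={})
        with caplog.at_level("WARNING"):
            row_df = ga.annotate(
                make_summary("s", ["rs1"], ["1"], [3000], [0.5]), model
            ).df
        assert row_df.iloc[0]["category"] == "exonic"
        assert "coarse mode" in caplog.text


class TestSelectTopGenes:
    def test_intronic_snps_do_not_score_genes(self):
        model = simple_model()
        s = make_summary(
            "s", ["rs1", "rs2", "rs3"], ["1"] * 3, [1500, 3000, 4500],
            [0.01, 1e-6, 0.3],
        )
        ann = ga.annotate(s, model)
        top = ga.select_top_genes(s, ann, k=10)
        assert top.df.iloc[0]["gene_id"] == "GENE1"
        assert top.df.iloc[0]["best_pvalue"] == 0.01  # the intronic 1e-6 is excluded

    def test_k_truncates_by_best_pvalue(self):
        model = simple_model()
        s = make_summary(
            "s", ["rs1", "rs2"], ["1", "1"], [1500, 21000], [1e-5, 1e-8]
        )
        ann = ga.annotate(s, model)
        top = ga.select_top_genes(s, ann, k=1)
        assert list(top.df["gene_id"]) == ["GENE2"]

    def test_matches_sort_oracle_on_planted_scores(self):
        rng = np.random.default_rng(2)
        n_genes = 120
        starts = np.arange(n_genes) * 10_000
        genes = pd.DataFrame(
            {
                "gene_id": [f"G{i:03d}" for i in range(n_genes)],
                "gene_symbol": [f"G{i:03d}" for i in range(n_genes)],
                "chrom": "1",
                "start0": starts,
                "end0": starts + 5000,
                "strand": "+",
            }
        )
        model = ga.GeneModel(genes=genes, exons={})  # coarse: all in-span = exonic
        planted = rng.uniform(1e-10, 1, n_genes)
        s = make_summary(
            "s", [f"rs{i}" for i in range(n_genes)], ["1"] * n_genes,
            starts + 100 + 1, planted,
        )
        ann = ga.annotate(s, model)
        top = ga.select_top_genes(s, ann, k=50)
        expected = [f"G{i:03d}" for i in np.argsort(planted, kind="stable")[:50]]
        assert list(top.df["gene_id"]) == expected

    def test_invariant_under_snp_order(self):
        rng = np.random.default_rng(3)
        model = simple_model()
        pos = rng.integers(1, 30_000, 200)
        s = make_summary("s", [f"rs{i}" for i in range(200)], ["1"] * 200, pos,
                         rng.random(200))
        perm = rng.permutation(200)
        s_shuf = make_summary("s", [f"rs{i}" for i in perm], ["1"] * 200, pos[perm],
                              s.df["pvalue"].to_numpy()[perm])
        top1 = ga.select_top_genes(s, ga.annotate(s, model), k=5)
        top2 = ga.select_top_genes(s_shuf, ga.annotate(s_shuf, model), k=5)
        pd.testing.assert_frame_equal(top1.df, top2.df)


class TestSnpTypeProportions:
    def test_arithmetic(self):
        df = pd.DataFrame(
            {
                "snp_id": ["a", "b", "c", "d"],
                "category": ["intergenic", "intergenic", "exonic", "intronic"],
                "gene_id": ["", "", "g", "g"],
                "distance": [0, 0, 0, 0],
            }
        )
        props = ga.snp_type_proportions(ga.AnnotationTable(df=df))
        by_cat = dict(zip(props["category"], props["proportion"]))
        assert by_cat == {
            "exonic": 0.25, "intronic": 0.25, "upstream": 0.0,
            "downstream": 0.0, "intergenic": 0.5,
        }
        assert props["proportion"].sum() == pytest.approx(1.0)

    def test_all_intergenic(self):
        df = pd.DataFrame(
            {"snp_id": ["a"], "category": ["intergenic"], "gene_id": [""],
             "distance": [0]}
        )
        props = ga.snp_type_proportions(ga.AnnotationTable(df=df))
        assert dict(zip(props["category"], props["proportion"]))["intergenic"] == 1.0

    def test_matches_tally_oracle(self):
        rng = np.random.default_rng(4)
        cats = rng.choice(list(ga.CATEGORIES), 10_000)
        df = pd.DataFrame(
            {"snp_id": [f"rs{i}" for i in range(10_000)], "category": cats,
             "gene_id": "", "distance": 0}
        )
        props = ga.snp_type_proportions(ga.AnnotationTable(df=df))
        for cat in ga.CATEGORIES:
            assert props.loc[props["category"] == cat, "count"].item() == (cats == cat).sum()


class TestGeneModelIO:
    def test_bed12_round_trip(self, tmp_path):
        model = simple_model()
        path = tmp_path / "genes.bed"
        ga.write_gene_model_bed(model, path)
        back = ga.read_gene_model(path)
        pd.testing.assert_frame_equal(
            model.genes.sort_values("gene_id").reset_index(drop=True),
            back.genes.sort_values("gene_id").reset_index(drop=True),
        )
        assert back.exons == model.exons

    def test_gff3_reader(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t1001\t5000\t.\t+\t.\tID=GENE1;Name=FOO\n"
            "1\tsrc\texon\t1001\t2000\t.\t+\t.\tID=GENE1.e1;Parent=GENE1\n"
            "1\tsrc\texon\t4001\t5000\t.\t+\t.\tID=GENE1.e2;Parent=GENE1\n"
        )
        model = ga.read_gene_model(path)
        row = model.genes.iloc[0]
        assert (row["gene_id"], row["gene_symbol"]) == ("GENE1", "FOO")
        assert (row["start0"], row["end0"]) == (1000, 5000)
        assert model.exons["GENE1"] == [(1000, 2000), (4000, 5000)]

    def test_gene_list_reader(self, tmp_path):
        path = tmp_path / "genes.txt"
        path.write_text("# region genes\nTBX1\n\nCOMT\n")
        assert ga.read_gene_list(path) == ["TBX1", "COMT"]
        empty = tmp_path / "empty.txt"
        empty.write_text("\n")
        with pytest.raises(InputError):
            ga.read_gene_list(empty)
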