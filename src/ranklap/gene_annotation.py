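"""Windowed SNP-to-gene annotation against a local gene model.

Each SNP is classified as exonic, intronic, upstream, downstream, or
intergenic relative to a gene model (BED12 or GFF3), with upstream and
downstream defined by a flanking window (default 1,000 bp, the common
variant-annotator convention) and named relative to gene strand.
Category priority is exonic > intronic > upstream/downstream > intergenic;
ties between overlapping genes go to the nearest gene-span midpoint, then
lexicographic gene id.

Gene lists for the network stage are built from the annotations: a gene's
score is the minimum p-value over its assigned SNPs in the exonic /
upstream / downstream categories — intronic SNPs carry their host gene id
but are excluded from gene-list construction, and intergenic SNPs are
assigned to no gene.

Coordinates: BED input is 0-based half-open, GFF3 is 1-based inclusive;
both are normalized to 0-based half-open internally, and all outputs are
1-based inclusive to match GWAS convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ranklap.errors import ConfigError, InputError
from ranklap.gwas_io import GwasSummary, normalize_chrom

logger = logging.getLogger(__name__)

CATEGORIES = ("exonic", "intronic", "upstream", "downstream", "intergenic")
DEFAULT_WINDOW = 1000
DEFAULT_TOP_K = 100


@dataclass
class GeneModel:
    """Gene spans plus optional exon intervals, 0-based half-open internally.

    ``genes`` columns: gene_id, gene_symbol, chrom, start0, end0, strand.
    ``exons`` maps gene_id -> list of (start0, end0).  When a gene has no
    exon record, the whole span is treated as exonic (coarse mode; logged).
    """

    genes: pd.DataFrame = field(repr=False)
    exons: dict[str, list[tuple[int, int]]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise InputError("gene model is empty")
        if self.genes["gene_id"].duplicated().any():
            raise InputError("duplicate gene_id in gene model")
        bad = self.genes["start0"] >= self.genes["end0"]
        if bad.any():
            raise InputError("gene model has start >= end")
        spans = {
            r.gene_id: (r.start0, r.end0) for r in self.genes.itertuples(index=False)
        }
        for gid, ivs in self.exons.items():
            if gid not in spans:
                raise InputError(f"exon for unknown gene_id {gid!r}")
            lo, hi = spans[gid]
            if any(s0 < lo or e0 > hi for s0, e0 in ivs):
                raise InputError(f"exon outside gene span for {gid!r}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class AnnotationTable:
    """Per-SNP annotation. Columns: snp_id, category, gene_id, distance.

    ``gene_id`` is empty for intergenic SNPs; ``distance`` is 0 for SNPs
    inside the gene span and the bp offset beyond the span otherwise.
    """

    df: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class TopGeneList:
    """Top genes of one study, ordered by ascending best SNP p-value.

    Columns: gene_id, best_snp_id, best_pvalue; ties broken by gene_id.
    """

    study_label: str
    df: pd.DataFrame = field(repr=False)
    k: int = DEFAULT_TOP_K

    def __len__(self) -> int:
        return len(self.df)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df["gene_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- readers

def read_gene_model(path: str | Path, fmt: str | None = None) -> GeneModel:
    """Read a gene model from BED (BED6/BED12) or GFF3.

    ``fmt`` is inferred from the suffix when omitted ("bed" / "gff"/"gff3").
    BED12 block fields populate exon intervals; GFF3 exons are collected
    from ``exon`` features under each ``gene``.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"gene model not found: {path}")
    if fmt is None:
        suffix = path.suffix.lower().lstrip(".")
        fmt = {"bed": "bed", "gff": "gff3", "gff3": "gff3", "gtf": "gff3"}.get(suffix)
        if fmt is None:
            raise ConfigError(f"cannot infer gene-model format from {path.name}")
    if fmt == "bed":
        return _read_bed(path)
    return _read_gff3(path)


def _read_bed(path: Path) -> GeneModel:
    rows, exons = [], {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 4:
            raise InputError(f"{path.name}: BED needs >= 4 columns")
        chrom = str(normalize_chrom(pd.Series([f[0]]))[0])
        start0, end0 = int(f[1]), int(f[2])
        gene_id = f[3]
        strand = f[5] if len(f) > 5 else "+"
        rows.append((gene_id, gene_id, chrom, start0, end0, strand))
        if len(f) >= 12:  # BED12 blocks are the exons
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons[gene_id] = [(start0 + s, start0 + s + sz) for s, sz in zip(starts, sizes)]
    genes = pd.DataFrame(
        rows, columns=["gene_id", "gene_symbol", "chrom", "start0", "end0", "strand"]
    )
    return GeneModel(genes=genes, exons=exons)


def _read_gff3(path: Path) -> GeneModel:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows, exons = [], {}
    for gene in db.features_of_type("gene"):
        gid = gene.id
        symbol = gene.attributes.get("Name", [gid])[0]
        chrom = str(normalize_chrom(pd.Series([gene.seqid]))[0])
        rows.append((gid, symbol, chrom, gene.start - 1, gene.end, gene.strand or "+"))
        ex = [
            (e.start - 1, e.end)
            for e in db.children(gene, featuretype="exon", order_by="start")
        ]
        if ex:
            exons[gid] = ex
    if not rows:
        raise InputError(f"{path.name}: no gene features")
    genes = pd.DataFrame(
        rows, columns=["gene_id", "gene_symbol", "chrom", "start0", "end0", "strand"]
    )
    return GeneModel(genes=genes, exons=exons)


def write_gene_model_bed(model: GeneModel, path: str | Path) -> None:
    """Write the model as BED12 (block fields carry the exons)."""
    lines = []
    for row in model.genes.itertuples(index=False):
        ex = model.exons.get(row.gene_id, [(row.start0, row.end0)])
        sizes = ",".join(str(e - s) for s, e in ex)
        starts = ",".join(str(s - row.start0) for s, e in ex)
        lines.append(
            "\t".join(
                [
                    row.chrom, str(row.start0), str(row.end0), row.gene_id, "0",
                    row.strand, str(row.start0), str(row.end0), "0",
                    str(len(ex)), sizes, starts,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list, one symbol per line; blank lines and # skipped."""
    out = [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not out:
        raise InputError(f"gene list {path} is empty")
    return out


# ------------------------------------------------------------- annotation

_PRIORITY = {"exonic": 0, "intronic": 1, "upstream": 2, "downstream": 2}


def _classify_against_gene(
    pos0: int, row, exons: list[tuple[int, int]] | None, window: int
) -> tuple[str, int] | None:
    """Category and distance of one SNP vs one gene, or None if unrelated."""
    start0, end0 = row.start0, row.end0
    if start0 <= pos0 < end0:
        if exons is None:  # coarse mode: whole span counts as exonic
            return "exonic", 0
        inside_exon = any(s <= pos0 < e for s, e in exons)
        return ("exonic" if inside_exon else "intronic"), 0
    if pos0 < start0:
        dist = start0 - pos0
        side_is_5prime = row.strand != "-"
    else:
        dist = pos0 - end0 + 1
        side_is_5prime = row.strand == "-"
    if dist > window:
        return None
    return ("upstream" if side_is_5prime else "downstream"), dist


def annotate(
    summary: GwasSummary, model: GeneModel, window: int = DEFAULT_WINDOW
) -> AnnotationTable:
    """Annotate every SNP of a study against the gene model.

    Every SNP gets exactly one category; candidate genes are found with an
    interval index over window-extended gene spans, then ranked by category
    priority, distance to span midpoint, and gene id.
    """
    if window < 0:
        raise ConfigError("window must be >= 0")
    if len(model) == 0:
        raise InputError("gene model is empty")
    coarse = not model.exons
    if coarse:
        logger.warning(
            "gene model has no exon intervals: whole spans classified exonic (coarse mode)"
        )

    trees: dict[str, IntervalTree] = {}
    rows_by_idx = list(model.genes.itertuples(index=False))
    for idx, row in enumerate(rows_by_idx):
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start0 - window, row.end0 + window, idx
        )

    snp_ids = summary.df["snp_id"].to_numpy()
    chroms = summary.df["chrom"].to_numpy()
    pos0s = summary.df["pos"].to_numpy() - 1  # to 0-based

    cats = np.full(len(snp_ids), "intergenic", dtype=object)
    genes = np.full(len(snp_ids), "", dtype=object)
    dists = np.zeros(len(snp_ids), dtype=np.int64)

    for i in range(len(snp_ids)):
        tree = trees.get(chroms[i])
        if tree is None:
            continue
        best = None
        for iv in tree.at(int(pos0s[i])):
            row = rows_by_idx[iv.data]
            ex = None if coarse else model.exons.get(row.gene_id, [])
            hit = _classify_against_gene(int(pos0s[i]), row, ex, window)
            if hit is None:
                continue
            cat, dist = hit
            mid_dist = abs((row.start0 + row.end0) / 2 - pos0s[i])
            key = (_PRIORITY[cat], mid_dist, row.gene_id)
            if best is None or key < best[0]:
                best = (key, cat, dist, row.gene_id)
        if best is not None:
            _, cats[i], dists[i], genes[i] = best

    df = pd.DataFrame(
        {"snp_id": snp_ids, "category": cats, "gene_id": genes, "distance": dists}
    )
    return AnnotationTable(df=df)


def select_top_genes(
    summary: GwasSummary,
    annotations: AnnotationTable,
    k: int = DEFAULT_TOP_K,
    score: str = "min_p",
) -> TopGeneList:
    """Top-k genes by ascending best assigned-SNP p-value.

    Only exonic/upstream/downstream assignments contribute.  ``score`` may
    be ``"min_p"`` (default: gene score is its smallest SNP p) or
    ``"n_significant"`` (count of assigned SNPs with p < 5e-8, descending).
    """
    merged = annotations.df.merge(
        summary.df[["snp_id", "pvalue"]], on="snp_id", how="inner"
    )
    eligible = merged[merged["category"].isin(["exonic", "upstream", "downstream"])]
    if len(eligible) == 0:
        raise InputError("no SNPs assigned to genes in eligible categories")
    if score == "min_p":
        idx = eligible.groupby("gene_id")["pvalue"].idxmin()
        per_gene = eligible.loc[idx, ["gene_id", "snp_id", "pvalue"]]
        per_gene = per_gene.rename(
            columns={"snp_id": "best_snp_id", "pvalue": "best_pvalue"}
        ).sort_values(["best_pvalue", "gene_id"], kind="mergesort")
    elif score == "n_significant":
        counts = (
            eligible.assign(sig=eligible["pvalue"] < 5e-8)
            .groupby("gene_id")
            .agg(best_pvalue=("pvalue", "min"), n_sig=("sig", "sum"))
            .reset_index()
        )
        best = eligible.loc[eligible.groupby("gene_id")["pvalue"].idxmin(), ["gene_id", "snp_id"]]
        per_gene = counts.merge(best.rename(columns={"snp_id": "best_snp_id"}), on="gene_id")
        per_gene = per_gene.sort_values(
            ["n_sig", "best_pvalue", "gene_id"], ascending=[False, True, True], kind="mergesort"
        )[["gene_id", "best_snp_id", "best_pvalue"]]
    else:
        raise ConfigError(f"unknown gene score {score!r}")
    if len(per_gene) < k:
        logger.warning(
            "%s: only %d eligible genes (< k=%d)", summary.study_label, len(per_gene), k
        )
    return TopGeneList(
        study_label=summary.study_label,
        df=per_gene.head(k).reset_index(drop=True),
        k=k,
    )


def snp_type_proportions(annotations: AnnotationTable) -> pd.DataFrame:
    """Counts and proportions per SNP category (all five always reported)."""
    if len(annotations) == 0:
        raise InputError("no annotations")
    counts = annotations.df["category"].value_counts()
    n = len(annotations)
    return pd.DataFrame(
        {
            "category": CATEGORIES,
            "count": [int(counts.get(c, 0)) for c in CATEGORIES],
            "proportion": [counts.get(c, 0) / n for c in CATEGORIES],
        }
    )
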