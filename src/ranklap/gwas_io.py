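"""Reading, validating, and harmonizing GWAS summary-statistic tables.

A GWAS summary table is tab-delimited text with a header; column names vary
between sources, so every semantic field (SNP identifier, chromosome,
position, p-value, odds ratio) is mapped explicitly via a ``column_map``.
Rows with unparseable or out-of-range p-values are dropped and counted.

Chromosomes are normalized to canonical form ``"1".."22", "X", "Y", "MT"``
(a leading ``chr`` prefix is stripped).  Only p-values and odds ratios are
used downstream — no allele harmonization or strand checks are performed,
because the rank-overlap statistic never looks at effect direction per
allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ranklap.errors import ConfigError, InputError

logger = logging.getLogger(__name__)

AUTOSOMES = tuple(str(i) for i in range(1, 23))
CANONICAL_CHROMS = AUTOSOMES + ("X", "Y", "MT")
#: sort order used for deterministic genomic ordering
CHROM_ORDER: dict[str, int] = {c: i for i, c in enumerate(CANONICAL_CHROMS)}

#: semantic fields of a summary table; odds_ratio may be absent/missing
REQUIRED_FIELDS = ("snp_id", "chrom", "pos", "pvalue")
OPTIONAL_FIELDS = ("odds_ratio",)


def normalize_chrom(values: pd.Series) -> pd.Series:
    """Strip ``chr`` prefixes and map 23/24/25 to X/Y/MT."""
    s = values.astype(str).str.strip().str.replace("^chr", "", regex=True)
    return s.replace({"23": "X", "24": "Y", "25": "MT", "M": "MT"})


@dataclass
class GwasSummary:
    """One study's per-SNP summary records.

    ``df`` has columns ``snp_id, chrom, pos, pvalue, odds_ratio`` with unique
    ``snp_id``, ``pvalue`` in (0, 1], 1-based positions, and canonical
    chromosome names.  ``odds_ratio`` may contain NaN.
    """

    study_label: str
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.df) == 0:
            raise InputError(f"study {self.study_label!r}: no SNP records")
        if self.df["snp_id"].duplicated().any():
            raise InputError(f"study {self.study_label!r}: duplicate snp_id")
        p = self.df["pvalue"].to_numpy()
        if not ((p > 0) & (p <= 1)).all():
            raise InputError(f"study {self.study_label!r}: p-values outside (0, 1]")
        if (self.df["pos"].to_numpy() < 1).any():
            raise InputError(f"study {self.study_label!r}: positions must be >= 1")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> pd.Series:
        return self.df["snp_id"]


@dataclass
class PairedSnpTable:
    """SNPs present in both studies, with both studies' p-values.

    Rows are sorted by (chrom, pos, snp_id); chromosome and position are
    taken from study A.  Columns: ``snp_id, chrom, pos, pvalue_a, pvalue_b``.
    """

    df: pd.DataFrame = field(repr=False)
    label_a: str = "a"
    label_b: str = "b"

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, label_a: str = "a", label_b: str = "b") -> "PairedSnpTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(df=df, label_a=label_a, label_b=label_b)


def read_gwas_summary(
    path: str | Path,
    column_map: Mapping[str, str],
    study_label: str | None = None,
) -> GwasSummary:
    """Read a tab-delimited summary-statistics file (gzip accepted).

    Parameters
    ----------
    path:
        File path; ``.gz`` suffixes are decompressed transparently.
    column_map:
        Maps semantic field names (``snp_id, chrom, pos, pvalue``, optionally
        ``odds_ratio``) to column names in the file's header.
    study_label:
        Defaults to the file's stem.

    Rows with unparseable p, p <= 0, or p > 1 are dropped (counted in the
    log).  Duplicate ``snp_id`` values keep the record with the smallest p.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"summary file not found: {path}")
    missing = [f for f in REQUIRED_FIELDS if f not in column_map]
    if missing:
        raise ConfigError(f"column_map missing required fields: {missing}")

    usecols = list(column_map.values())
    df = pd.read_csv(path, sep="\t", usecols=lambda c: c in usecols, dtype=str)
    absent = [c for c in usecols if c not in df.columns]
    if absent:
        raise ConfigError(f"{path}: mapped columns not in header: {absent}")

    df = df.rename(columns={v: k for k, v in column_map.items()})
    n_raw = len(df)

    out = pd.DataFrame(
        {
            "snp_id": df["snp_id"].astype(str),
            "chrom": normalize_chrom(df["chrom"]),
            "pos": pd.to_numeric(df["pos"], errors="coerce"),
            "pvalue": pd.to_numeric(df["pvalue"], errors="coerce"),
            "odds_ratio": pd.to_numeric(df["odds_ratio"], errors="coerce")
            if "odds_ratio" in df.columns
            else np.nan,
        }
    )
    valid = (
        out["pvalue"].notna()
        & (out["pvalue"] > 0)
        & (out["pvalue"] <= 1)
        & out["pos"].notna()
        & (out["pos"] >= 1)
        & (out["snp_id"].str.len() > 0)
    )
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("%s: dropped %d/%d rows with invalid p/pos", path.name, n_dropped, n_raw)
    out = out[valid].copy()
    out["pos"] = out["pos"].astype(np.int64)

    n_dup = int(out["snp_id"].duplicated().sum())
    if n_dup:
        logger.warning("%s: %d duplicate snp_ids; keeping smallest p each", path.name, n_dup)
        out = out.sort_values(["snp_id", "pvalue"], kind="mergesort").drop_duplicates(
            "snp_id", keep="first"
        )

    if len(out) == 0:
        raise InputError(f"{path}: no valid rows after filtering")
    out = out.reset_index(drop=True)
    return GwasSummary(study_label=study_label or path.stem.split(".")[0], df=out)


def write_gwas_summary(summary: GwasSummary, path: str | Path) -> None:
    """Write a summary back to tab-delimited text in canonical columns."""
    summary.df.to_csv(path, sep="\t", index=False)


def _genomic_sort(df: pd.DataFrame) -> pd.DataFrame:
    key = df["chrom"].map(lambda c: CHROM_ORDER.get(c, len(CHROM_ORDER)))
    order = np.lexsort(
        (df["snp_id"].to_numpy(), df["pos"].to_numpy(), key.to_numpy())
    )
    return df.iloc[order].reset_index(drop=True)


def intersect_studies(a: GwasSummary, b: GwasSummary) -> PairedSnpTable:
    """Intersect the two studies' SNP sets on identifier.

    Coordinates come from study A; rows are deterministically ordered by
    (chrom, pos, snp_id).  An empty intersection is an error.
    """
    merged = a.df.merge(
        b.df[["snp_id", "pvalue"]].rename(columns={"pvalue": "pvalue_b"}),
        on="snp_id",
        how="inner",
    ).rename(columns={"pvalue": "pvalue_a"})
    if len(merged) == 0:
        raise InputError(
            f"no shared SNPs between {a.study_label!r} and {b.study_label!r}"
        )
    merged = merged[["snp_id", "chrom", "pos", "pvalue_a", "pvalue_b"]]
    logger.info(
        "intersection of %s (%d) and %s (%d): %d shared SNPs",
        a.study_label, len(a), b.study_label, len(b), len(merged),
    )
    return PairedSnpTable(df=_genomic_sort(merged), label_a=a.study_label, label_b=b.study_label)


def filter_for_gene_selection(g: GwasSummary) -> GwasSummary:
    """Keep autosomal records with odds ratio strictly greater than one.

    Records on sex chromosomes and records with missing OR are dropped; the
    OR > 1 cut removes variants with a pseudo-protective direction before
    gene selection.  Idempotent.
    """
    df = g.df
    keep = df["chrom"].isin(AUTOSOMES) & (df["odds_ratio"] > 1)
    out = df[keep].reset_index(drop=True)
    logger.info(
        "%s: gene-selection filter kept %d/%d records (autosomal, OR>1)",
        g.study_label, len(out), len(df),
    )
    if len(out) == 0:
        logger.warning("%s: gene-selection filter left no records", g.study_label)
        # bypass the nonempty invariant deliberately: empty is a legal result here
        obj = GwasSummary.__new__(GwasSummary)
        obj.study_label = g.study_label
        obj.df = out
        return obj
    return GwasSummary(study_label=g.study_label, df=out)
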