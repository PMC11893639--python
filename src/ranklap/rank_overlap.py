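"""Rank-binned cross-table statistic for SNP-level overlap of two studies.

Both studies' shared SNPs are ranked by significance (rank 1 = least
significant, rank N = most significant, ranking on -log10 p), cut into
``B`` equal-count bins per study (default 30), and cross-tabulated into a
B x B count matrix.  Under the null of no shared signal the counts are an
equal-margin multinomial around N/B^2; tail dependence between the studies
shows up as excess counts in cells where both bins are high — the
upper-right quadrant when bin B holds the most significant SNPs.

Per-cell z-scores standardize each count by the mean and sample standard
deviation of all B^2 counts; cells with |z| above a threshold (default 4)
and a Bonferroni-corrected normal two-tail p below alpha are called
significant.  A permutation test (shuffling one study's bin labels)
provides a distribution-free sensitivity analysis of the joint pattern.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ranklap.errors import ConfigError, InputError
from ranklap.gwas_io import CHROM_ORDER, PairedSnpTable

logger = logging.getLogger(__name__)

DEFAULT_BINS = 30
DEFAULT_Z_THRESHOLD = 4.0
DEFAULT_N_PERM = 20_000

Statistic = Literal["max_quadrant_z", "quadrant_exceedance"]


@dataclass
class PairedRanks:
    """Per-SNP significance ranks and bin labels for both studies.

    Ranks are a permutation of 1..N per study; ``bin_b_of_rank(r) =
    floor((r-1)*B/N) + 1`` so bin sizes differ by at most one and bin B
    contains the most significant SNPs.
    """

    rank_a: np.ndarray
    rank_b: np.ndarray
    bin_a: np.ndarray
    bin_b: np.ndarray
    n_snps: int
    n_bins: int
    snp_id: np.ndarray | None = None
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None


@dataclass
class PermutationResult:
    pvalue: float
    observed: float
    null_sample: np.ndarray = field(repr=False)
    statistic: str = "max_quadrant_z"
    n_perm: int = 0
    seed: int | None = None


@dataclass
class CrossTableResult:
    """Counts, z-scores and significance calls for one study pair."""

    counts: np.ndarray
    mean_count: float
    sd_count: float
    zscores: np.ndarray
    significant_cells: pd.DataFrame  # columns: bin_a, bin_b, z, p_bonferroni
    permutation: PermutationResult | None = None

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return int(self.counts.sum())


def rank_by_significance(
    table: PairedSnpTable, study: Literal["a", "b"]
) -> np.ndarray:
    """Rank SNPs by -log10 p: rank 1 = largest p, rank N = smallest p.

    Ties are broken by (chrom, pos, snp_id) ascending — the earlier genomic
    key gets the lower (less significant) rank — so ranking is deterministic
    and seed-independent.
    """
    if study not in ("a", "b"):
        raise ConfigError(f"study selector must be 'a' or 'b', got {study!r}")
    df = table.df
    p = df[f"pvalue_{study}"].to_numpy(dtype=float)
    if not ((p > 0) & (p <= 1)).all():
        raise InputError("p-values must lie in (0, 1]")
    neglogp = -np.log10(p)
    chrom_key = df["chrom"].map(lambda c: CHROM_ORDER.get(c, len(CHROM_ORDER))).to_numpy()
    order = np.lexsort(
        (df["snp_id"].to_numpy(), df["pos"].to_numpy(), chrom_key, neglogp)
    )
    ranks = np.empty(len(p), dtype=np.int64)
    ranks[order] = np.arange(1, len(p) + 1)
    return ranks


def assign_bins(ranks: np.ndarray, n_snps: int, n_bins: int = DEFAULT_BINS) -> np.ndarray:
    """Cut ranks 1..N into B equal-count bins: bin = floor((r-1)B/N) + 1.

    Bin sizes differ by at most one; bin ``n_bins`` holds the most
    significant SNPs.
    """
    if n_bins < 2:
        raise ConfigError(f"need at least 2 bins, got {n_bins}")
    if n_snps < n_bins:
        raise InputError(f"cannot cut {n_snps} SNPs into {n_bins} bins")
    ranks = np.asarray(ranks, dtype=np.int64)
    return (ranks - 1) * n_bins // n_snps + 1


def cross_table(bins_a: np.ndarray, bins_b: np.ndarray, n_bins: int) -> np.ndarray:
    """B x B count matrix C[i, j] = #{SNPs with bin_a = i+1, bin_b = j+1}."""
    bins_a = np.asarray(bins_a, dtype=np.int64)
    bins_b = np.asarray(bins_b, dtype=np.int64)
    if bins_a.shape != bins_b.shape:
        raise InputError("bin vectors must have equal length")
    for v, name in ((bins_a, "bins_a"), (bins_b, "bins_b")):
        if v.min(initial=1) < 1 or v.max(initial=n_bins) > n_bins:
            raise InputError(f"{name} outside 1..{n_bins}")
    flat = (bins_a - 1) * n_bins + (bins_b - 1)
    return np.bincount(flat, minlength=n_bins * n_bins).reshape(n_bins, n_bins)


def cell_zscores(counts: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Standardize counts by the mean and sample SD over all B^2 cells.

    Returns ``(z, mean, sd)`` with sd the sample standard deviation
    (denominator B^2 - 1); a constant table yields all-zero z.
    """
    c = np.asarray(counts, dtype=float)
    if c.size < 2:
        raise InputError("need at least 2 cells")
    m = float(c.mean())
    s = float(c.std(ddof=1))
    if s == 0.0:
        return np.zeros_like(c), m, s
    return (c - m) / s, m, s


def bonferroni_p(z: float | np.ndarray, n_cells: int) -> np.ndarray:
    """Two-sided normal tail p, Bonferroni-corrected for ``n_cells`` tests."""
    raw = 2.0 * stats.norm.sf(np.abs(z))
    return np.minimum(1.0, n_cells * raw)


def call_significant_cells(
    zscores: np.ndarray,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cells with |z| > z_threshold AND Bonferroni p < alpha.

    The Bonferroni family is all B^2 cells, two-sided.  Output columns
    ``bin_a, bin_b, z, p_bonferroni`` (1-based bins), sorted by corrected p
    ascending, ties by (bin_a, bin_b).
    """
    z = np.asarray(zscores, dtype=float)
    if not np.isfinite(z).all():
        raise InputError("z matrix contains non-finite values")
    n_cells = z.size
    ii, jj = np.nonzero(np.abs(z) > z_threshold)
    pb = bonferroni_p(z[ii, jj], n_cells)
    keep = pb < alpha
    df = pd.DataFrame(
        {
            "bin_a": ii[keep] + 1,
            "bin_b": jj[keep] + 1,
            "z": z[ii, jj][keep],
            "p_bonferroni": pb[keep],
        }
    )
    return df.sort_values(
        ["p_bonferroni", "bin_a", "bin_b"], kind="mergesort"
    ).reset_index(drop=True)


def quadrant_mask(n_bins: int) -> np.ndarray:
    """Boolean mask of the upper-right quadrant: both bins > B/2."""
    hi = np.arange(1, n_bins + 1) > n_bins / 2
    return np.outer(hi, hi)


def _statistic_value(
    z: np.ndarray, mask: np.ndarray, statistic: Statistic, z_threshold: float
) -> float:
    if statistic == "max_quadrant_z":
        return float(z[mask].max())
    if statistic == "quadrant_exceedance":
        return float((z[mask] > z_threshold).sum())
    raise ConfigError(f"unknown permutation statistic {statistic!r}")


def permutation_test(
    pairs: PairedRanks,
    statistic: Statistic = "max_quadrant_z",
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = 0,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> PermutationResult:
    """Permutation sensitivity analysis of the upper-right-quadrant pattern.

    Each permutation shuffles study B's bin labels across SNPs (study A
    fixed), rebuilds the cross table and z matrix, and evaluates the test
    statistic: by default the maximum z over the quadrant with both bins
    above B/2, alternatively the count of quadrant cells with z above
    ``z_threshold``.  The p-value uses the add-one estimator
    ``(1 + #{T_perm >= T_obs}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ConfigError(f"n_perm must be >= 1, got {n_perm}")
    B = pairs.n_bins
    mask = quadrant_mask(B)
    obs_counts = cross_table(pairs.bin_a, pairs.bin_b, B)
    z_obs, _, _ = cell_zscores(obs_counts)
    t_obs = _statistic_value(z_obs, mask, statistic, z_threshold)

    rng = np.random.default_rng(seed)
    idx_a = (pairs.bin_a - 1) * B
    bins_b0 = pairs.bin_b - 1
    ncell = B * B
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm_b = rng.permutation(bins_b0)
        c = np.bincount(idx_a + perm_b, minlength=ncell).astype(float)
        s = c.std(ddof=1)
        z = np.zeros(ncell) if s == 0 else (c - c.mean()) / s
        null[k] = _statistic_value(z.reshape(B, B), mask, statistic, z_threshold)

    pvalue = (1 + int((null >= t_obs).sum())) / (n_perm + 1)
    return PermutationResult(
        pvalue=pvalue,
        observed=t_obs,
        null_sample=null,
        statistic=statistic,
        n_perm=n_perm,
        seed=seed,
    )


def make_paired_ranks(table: PairedSnpTable, n_bins: int = DEFAULT_BINS) -> PairedRanks:
    """Rank and bin both studies of an intersected SNP table."""
    n = len(table)
    rank_a = rank_by_significance(table, "a")
    rank_b = rank_by_significance(table, "b")
    return PairedRanks(
        rank_a=rank_a,
        rank_b=rank_b,
        bin_a=assign_bins(rank_a, n, n_bins),
        bin_b=assign_bins(rank_b, n, n_bins),
        n_snps=n,
        n_bins=n_bins,
        snp_id=table.df["snp_id"].to_numpy(),
        chrom=table.df["chrom"].to_numpy(),
        pos=table.df["pos"].to_numpy(),
    )


def analyze_pair(
    table: PairedSnpTable,
    n_bins: int = DEFAULT_BINS,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    alpha: float = 0.05,
    n_perm: int | None = DEFAULT_N_PERM,
    seed: int | None = 0,
    statistic: Statistic = "max_quadrant_z",
) -> tuple[CrossTableResult, PairedRanks]:
    """Full first-stage analysis: ranks, bins, table, z, calls, permutation.

    Set ``n_perm=None`` to skip the permutation test.
    """
    pairs = make_paired_ranks(table, n_bins)
    counts = cross_table(pairs.bin_a, pairs.bin_b, n_bins)
    z, m, s = cell_zscores(counts)
    cells = call_significant_cells(z, z_threshold=z_threshold, alpha=alpha)
    perm = None
    if n_perm:
        perm = permutation_test(
            pairs, statistic=statistic, n_perm=n_perm, seed=seed, z_threshold=z_threshold
        )
    result = CrossTableResult(
        counts=counts,
        mean_count=m,
        sd_count=s,
        zscores=z,
        significant_cells=cells,
        permutation=perm,
    )
    return result, pairs


def _matrix_frame(mat: np.ndarray) -> pd.DataFrame:
    B = mat.shape[0]
    labels = [str(i) for i in range(1, B + 1)]
    return pd.DataFrame(mat, index=pd.Index(labels, name="bin_a"), columns=labels)


def export_heatmap(
    result: CrossTableResult, outdir: str | Path, basename: str = "cross_table"
) -> dict[str, Path]:
    """Write counts and z matrices as TSV plus a heatmap image.

    Bin 1 (least significant) sits at the origin and bin B (most
    significant) at the top-right; no reordering or dendrograms.  Returns
    the written paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / f"{basename}_counts.tsv",
        "zscores": outdir / f"{basename}_zscores.tsv",
        "heatmap": outdir / f"{basename}_heatmap.png",
        "significant": outdir / f"{basename}_significant_cells.tsv",
    }
    _matrix_frame(result.counts).to_csv(paths["counts"], sep="\t")
    _matrix_frame(result.zscores).to_csv(paths["zscores"], sep="\t")
    result.significant_cells.to_csv(paths["significant"], sep="\t", index=False)

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(result.zscores.T, origin="lower", cmap="Blues", aspect="auto")
    ax.set_xlabel("study A significance bin")
    ax.set_ylabel("study B significance bin")
    ax.set_title("cross-table z-scores (bin B = most significant)")
    fig.colorbar(im, ax=ax, label="z")
    fig.savefig(paths["heatmap"], dpi=120, metadata={"Software": None})
    plt.close(fig)

    if result.permutation is not None:
        perm_path = outdir / f"{basename}_permutation.json"
        p = result.permutation
        perm_path.write_text(
            json.dumps(
                {
                    "statistic": p.statistic,
                    "observed": p.observed,
                    "pvalue": p.pvalue,
                    "n_perm": p.n_perm,
                    "seed": p.seed,
                },
                indent=2,
            )
        )
        paths["permutation"] = perm_path
    logger.info("wrote cross-table outputs to %s", outdir)
    return paths


def thin_by_position(table: PairedSnpTable, step: int) -> PairedSnpTable:
    """Keep every ``step``-th SNP in genomic order — a crude guard against
    local LD inflating the cross-table counts.  Off by default."""
    if step < 1:
        raise ConfigError("thinning step must be >= 1")
    return PairedSnpTable(
        df=table.df.iloc[::step].reset_index(drop=True),
        label_a=table.label_a,
        label_b=table.label_b,
    )
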