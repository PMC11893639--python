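"""Calibration, power, and recovery experiments over the synthetic generator.

These routines run the pipeline's stages on simulated inputs with known
ground truth and summarize the outcomes (false-positive rates, detection
rates, localization, oracle deviations).  They back both the package's
acceptance-style tests and the reproduction script, so the measured
quantities are computed in exactly one place.

Independent oracles (brute-force cross tabulation, prefix-scan enrichment
running sum, exact-fraction hypergeometric enumeration) are implemented
here from first principles, deliberately not sharing code with the
production paths they check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ranklap import gwas_io, rank_overlap
from ranklap.network_enrichment import (
    InteractionNetwork,
    ScoredGeneList,
    gsea_preranked,
    overlap_profile,
)
from ranklap.pathway_map import PathwayDB, enrich, jaccard, stepdown_prune
from ranklap.synthetic import SimulationConfig, simulate_gwas_pair, simulate_network

logger = logging.getLogger(__name__)

#: latent mean giving shared-causal SNPs a median two-sided p of 1e-6
NONCENTRALITY_MEDIAN_P_1E6 = float(stats.norm.isf(0.5e-6))


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s % (2**31 - 1)) for s in ss.generate_state(n, dtype=np.uint64)]


# ------------------------------------------------------------------ stage 1

def brute_force_cross_table(
    p_a: np.ndarray,
    p_b: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    snp_id: np.ndarray,
    n_bins: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Independent reference implementation of ranks -> bins -> table -> z.

    Pure-python sort-based ranking with the documented tie-break, explicit
    double loop for the tally, and a literal mean/sample-SD z — no shared
    code with :mod:`ranklap.rank_overlap`.
    """
    n = len(p_a)

    def ranks(p):
        order = sorted(
            range(n), key=lambda i: (-p[i], int(chrom[i]), pos[i], snp_id[i])
        )
        r = [0] * n
        for rank0, i in enumerate(order):
            r[i] = rank0 + 1
        return r

    def bins(r):
        return [(ri - 1) * n_bins // n + 1 for ri in r]

    ba, bb = bins(ranks(p_a)), bins(ranks(p_b))
    counts = np.zeros((n_bins, n_bins), dtype=int)
    for i in range(n):
        counts[ba[i] - 1, bb[i] - 1] += 1
    flat = counts.ravel().astype(float)
    m = flat.mean()
    dev = flat - m
    s = float(np.sqrt((dev**2).sum() / (len(flat) - 1)))
    z = np.zeros_like(counts, dtype=float) if s == 0 else (counts - m) / s
    return counts, z


@dataclass
class StructuralSweep:
    n_instances: int
    conserved: bool
    marginals_ok: bool
    z_sum_max: float
    oracle_max_abs_dev: float
    n_oracle_instances: int


def structural_sweep(
    n_instances: int = 1000,
    n_oracle: int = 200,
    seed: int = 0,
    n_min: int = 900,
    n_max: int = 50_000,
) -> StructuralSweep:
    """Structural invariants over randomized paired-rank instances.

    Large instances (N in [n_min, n_max], B in 2..30) are checked for count
    conservation, near-equal marginals, and a centering z matrix; small
    instances (N <= 50, B <= 5) are compared cell-for-cell against the
    brute-force oracle.
    """
    rng = np.random.default_rng(seed)
    conserved = marginals_ok = True
    z_sum_max = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(n_min, n_max + 1))
        b = int(rng.integers(2, 31))
        rank_a = rng.permutation(n) + 1
        rank_b = rng.permutation(n) + 1
        bins_a = rank_overlap.assign_bins(rank_a, n, b)
        bins_b = rank_overlap.assign_bins(rank_b, n, b)
        counts = rank_overlap.cross_table(bins_a, bins_b, b)
        z, _, _ = rank_overlap.cell_zscores(counts)
        conserved &= int(counts.sum()) == n
        lo, hi = n // b, -(-n // b)
        row, col = counts.sum(axis=1), counts.sum(axis=0)
        marginals_ok &= bool(
            ((row >= lo) & (row <= hi)).all() and ((col >= lo) & (col <= hi)).all()
        )
        z_sum_max = max(z_sum_max, abs(float(z.sum())))

    max_dev = 0.0
    for _ in range(n_oracle):
        n = int(rng.integers(10, 51))
        b = int(rng.integers(2, 6))
        p_a = rng.random(n)
        p_b = rng.random(n)
        chrom = np.array([str(rng.integers(1, 23)) for _ in range(n)])
        pos = rng.integers(1, 10_000, size=n)
        snp_id = np.array([f"rs{i}" for i in range(n)])
        df = pd.DataFrame(
            {"snp_id": snp_id, "chrom": chrom, "pos": pos,
             "pvalue_a": p_a, "pvalue_b": p_b}
        )
        table = gwas_io.PairedSnpTable(df=df)
        pairs = rank_overlap.make_paired_ranks(table, b)
        counts = rank_overlap.cross_table(pairs.bin_a, pairs.bin_b, b)
        z, _, _ = rank_overlap.cell_zscores(counts)
        # oracle works on the same (sorted) row order as the table
        o_counts, o_z = brute_force_cross_table(
            df["pvalue_a"].to_numpy(), df["pvalue_b"].to_numpy(),
            df["chrom"].to_numpy(), df["pos"].to_numpy(), df["snp_id"].to_numpy(), b,
        )
        if (counts != o_counts).any():
            max_dev = np.inf
        max_dev = max(max_dev, float(np.abs(z - o_z).max()))
    return StructuralSweep(
        n_instances=n_instances,
        conserved=conserved,
        marginals_ok=marginals_ok,
        z_sum_max=z_sum_max,
        oracle_max_abs_dev=max_dev,
        n_oracle_instances=n_oracle,
    )


def _analyze_simulated_pair(
    cfg: SimulationConfig,
    seed: int,
    n_bins: int,
    n_perm: int | None,
    perm_seed: int | None = None,
):
    a, b, truth = simulate_gwas_pair(cfg, seed=seed)
    table = gwas_io.intersect_studies(a, b)
    result, pairs = rank_overlap.analyze_pair(
        table, n_bins=n_bins, n_perm=n_perm, seed=perm_seed
    )
    return result, pairs, truth


@dataclass
class NullCalibration:
    n_runs: int
    significant_cell_rate: float
    perm_pvalues: np.ndarray
    ks_statistic: float
    ks_pvalue: float


def null_calibration(
    n_runs: int = 200,
    n_snps: int = 50_000,
    n_bins: int = 30,
    n_perm: int = 500,
    seed: int = 0,
) -> NullCalibration:
    """False-positive rate and permutation-p uniformity under pi_null = 1."""
    seeds = _child_seeds(seed, 2 * n_runs)
    cfg = SimulationConfig(
        n_snps=n_snps, pi_null=1.0, pi_shared=0.0, pi_a_only=0.0, pi_b_only=0.0
    )
    n_sig = 0
    perm_p = np.empty(n_runs)
    for k in range(n_runs):
        result, _, _ = _analyze_simulated_pair(
            cfg, seeds[2 * k], n_bins, n_perm, perm_seed=seeds[2 * k + 1]
        )
        n_sig += int(len(result.significant_cells) > 0)
        perm_p[k] = result.permutation.pvalue
    ks = stats.kstest(perm_p, "uniform")
    return NullCalibration(
        n_runs=n_runs,
        significant_cell_rate=n_sig / n_runs,
        perm_pvalues=perm_p,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
    )


@dataclass
class PowerLocalization:
    n_runs: int
    detection_rate: float
    quadrant_cell_pct: float
    n_significant_cells: int


def power_localization(
    n_runs: int = 100,
    n_snps: int = 50_000,
    n_bins: int = 30,
    pi_shared: float = 0.01,
    shared_corr: float = 0.8,
    noncentrality: float = NONCENTRALITY_MEDIAN_P_1E6,
    seed: int = 0,
) -> PowerLocalization:
    """Detection rate and upper-right-quadrant localization with planted
    tail overlap (shared-causal SNPs at median p ~ 1e-6)."""
    seeds = _child_seeds(seed, n_runs)
    cfg = SimulationConfig(
        n_snps=n_snps,
        pi_null=1.0 - pi_shared,
        pi_shared=pi_shared,
        pi_a_only=0.0,
        pi_b_only=0.0,
        shared_corr=shared_corr,
        noncentrality=noncentrality,
    )
    detected = 0
    in_quadrant = total_cells = 0
    half = n_bins / 2
    for k in range(n_runs):
        result, _, _ = _analyze_simulated_pair(cfg, seeds[k], n_bins, None)
        cells = result.significant_cells
        detected += int(len(cells) > 0)
        total_cells += len(cells)
        in_quadrant += int(((cells["bin_a"] > half) & (cells["bin_b"] > half)).sum())
    return PowerLocalization(
        n_runs=n_runs,
        detection_rate=detected / n_runs,
        quadrant_cell_pct=100.0 * in_quadrant / total_cells if total_cells else float("nan"),
        n_significant_cells=total_cells,
    )


@dataclass
class DependenceRecovery:
    n_quadruples: int
    monotone_pct: float
    mean_max_z: dict[float, float]


def dependence_recovery(
    n_quadruples: int = 50,
    corrs: Sequence[float] = (0.0, 0.3, 0.6, 0.9),
    n_snps: int = 50_000,
    n_bins: int = 30,
    seed: int = 0,
) -> DependenceRecovery:
    """Matched-seed recovery of the planted dependence parameter.

    For each quadruple seed, the same dataset is regenerated at each
    shared_corr (common random numbers); the observed max z over the
    upper-right quadrant should increase along the corr grid.
    """
    seeds = _child_seeds(seed, n_quadruples)
    mask = rank_overlap.quadrant_mask(n_bins)
    monotone = 0
    max_z = {rho: [] for rho in corrs}
    for s in seeds:
        observed = []
        for rho in corrs:
            cfg = SimulationConfig(shared_corr=rho, n_snps=n_snps)
            result, _, _ = _analyze_simulated_pair(cfg, s, n_bins, None)
            t = float(result.zscores[mask].max())
            observed.append(t)
            max_z[rho].append(t)
        monotone += int(all(x < y for x, y in zip(observed, observed[1:])))
    return DependenceRecovery(
        n_quadruples=n_quadruples,
        monotone_pct=100.0 * monotone / n_quadruples,
        mean_max_z={rho: float(np.mean(v)) for rho, v in max_z.items()},
    )


# ------------------------------------------------------------------ stage 2

def es_prefix_oracle(
    ranked_scores: np.ndarray, hit_mask: np.ndarray, weight_exponent: float = 1.0
) -> float:
    """Literal running-sum enrichment score: walk the ranked list once,
    tracking the signed maximum deviation at every position."""
    n = len(ranked_scores)
    nh = int(hit_mask.sum())
    w = np.abs(ranked_scores) ** weight_exponent
    total = w[hit_mask].sum()
    if total == 0:
        w = np.ones(n)
        total = float(nh)
    running = 0.0
    hi = lo = 0.0
    for i in range(n):
        if hit_mask[i]:
            running += w[i] / total
        else:
            running -= 1.0 / (n - nh)
        hi = max(hi, running)
        lo = min(lo, running)
    # signed maximum deviation; ties resolve to the positive side
    return hi if hi >= -lo - 1e-9 else lo


@dataclass
class GseaOracleSweep:
    n_subsets: int
    max_abs_dev: float


def gsea_oracle_sweep(n_genes: int = 10, seed: int = 0) -> GseaOracleSweep:
    """ES agreement with the prefix-scan oracle over every proper nonempty
    subset of a small ranked list (2^n - 2 gene sets)."""
    rng = np.random.default_rng(seed)
    scores = np.sort(rng.random(n_genes))[::-1] + 0.1
    genes = np.array([f"g{i:02d}" for i in range(n_genes)])
    ranked = ScoredGeneList(df=pd.DataFrame({"gene_id": genes, "score": scores}))
    max_dev = 0.0
    count = 0
    for mask_bits in range(1, 2**n_genes - 1):
        hit_mask = np.array(
            [(mask_bits >> i) & 1 == 1 for i in range(n_genes)]
        )
        res = gsea_preranked(ranked, genes[hit_mask], n_perm=1, seed=0)
        oracle = es_prefix_oracle(scores, hit_mask)
        max_dev = max(max_dev, abs(res.es - oracle))
        count += 1
    return GseaOracleSweep(n_subsets=count, max_abs_dev=max_dev)


@dataclass
class NetworkOverlapExperiment:
    n_sims: int
    shared_detection_rate: float
    disjoint_flag_rate: float


def _profile_detects(df: pd.DataFrame) -> bool:
    """Significant at some size and persisting through the largest size."""
    sig = df.sort_values("size")["significant"].to_numpy()
    return bool(sig[-1]) and bool(sig.any())


def network_overlap_experiment(
    n_sims: int = 100,
    n_genes: int = 2_000,
    n_communities: int = 2,
    seed_size: int = 100,
    sizes: Sequence[int] = tuple(range(100, 1001, 100)),
    n_perm: int = 200,
    seed: int = 0,
) -> NetworkOverlapExperiment:
    """Detection and false-flag rates of the network-overlap profile.

    Per simulation one planted-partition network is generated; the
    reference set is sampled from community 0.  The *shared* query seed is
    a disjoint sample from the same community, the *disjoint* query seed a
    sample from community 1.  Detection requires the significance flag
    (ES > 0, BH-adjusted p < 0.05) to appear and persist through the
    largest expansion size; any flagged size counts as a false flag in the
    disjoint condition.

    Communities must hold at least ``max(sizes)`` genes (the default: two
    communities of 1000): greedy expansion necessarily leaves a smaller
    community once exhausted, and the planted shared/disjoint contrast is
    only well-defined while the expanded set can stay inside its
    community.
    """
    seeds = _child_seeds(seed, 4 * n_sims)
    cfg = SimulationConfig(n_genes=n_genes, n_communities=n_communities)
    detected = flagged = 0
    for k in range(n_sims):
        network, comm = simulate_network(cfg, seed=seeds[4 * k])
        rng = np.random.default_rng(seeds[4 * k + 1])
        comm0 = sorted(g for g, c in comm.items() if c == 0)
        comm1 = sorted(g for g, c in comm.items() if c == 1)
        picks = rng.choice(comm0, size=2 * seed_size, replace=False)
        reference = list(picks[:seed_size])
        query_shared = list(picks[seed_size:])
        query_disjoint = list(rng.choice(comm1, size=seed_size, replace=False))
        prof_s = overlap_profile(
            network, reference, query_shared, sizes=sizes,
            n_perm=n_perm, seed=seeds[4 * k + 2],
        )
        prof_d = overlap_profile(
            network, reference, query_disjoint, sizes=sizes,
            n_perm=n_perm, seed=seeds[4 * k + 3],
        )
        detected += int(_profile_detects(prof_s.df))
        flagged += int(bool(prof_d.df["significant"].any()))
    return NetworkOverlapExperiment(
        n_sims=n_sims,
        shared_detection_rate=detected / n_sims,
        disjoint_flag_rate=flagged / n_sims,
    )


# ------------------------------------------------------------------ stage 3

def hypergeom_exact_p(M: int, K: int, n: int, k: int) -> Fraction:
    """Exact upper-tail hypergeometric probability by full enumeration."""
    denom = comb(M, n)
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        if n - j <= M - K:
            total += Fraction(comb(K, j) * comb(M - K, n - j), denom)
    return total


@dataclass
class HypergeomSweep:
    n_configs: int
    max_abs_dev: float


def hypergeom_sweep(max_universe: int = 30) -> HypergeomSweep:
    """enrich() p-values vs exact-fraction enumeration, all (M, K, n, k)
    with universe size <= ``max_universe``.

    For each universe size M and query size n, one database holds a
    pathway for every feasible (K, k) pair, so a single enrich() call
    evaluates them all.
    """
    max_dev = 0.0
    n_configs = 0
    for M in range(2, max_universe + 1):
        genes = [f"u{i:02d}" for i in range(M)]
        for n in range(1, M + 1):
            query = genes[:n]
            outside = genes[n:]
            sets = {}
            expected = {}
            for K in range(1, M + 1):
                k_lo = max(0, n - (M - K))
                for k in range(k_lo, min(K, n) + 1):
                    if K - k > len(outside):
                        continue
                    pid = f"K{K:02d}k{k:02d}"
                    members = frozenset(query[:k]) | frozenset(outside[: K - k])
                    if len(members) != K:
                        continue
                    sets[pid] = (pid, members)
                    expected[pid] = float(hypergeom_exact_p(M, K, n, k))
            if not sets:
                continue
            db = PathwayDB(sets=sets, universe=frozenset(genes))
            res = enrich(query, db)
            for row in res.itertuples(index=False):
                max_dev = max(max_dev, abs(row.pvalue - expected[row.pathway_id]))
                n_configs += 1
    return HypergeomSweep(n_configs=n_configs, max_abs_dev=max_dev)


@dataclass
class PruneSweep:
    n_collections: int
    max_retained_jaccard: float
    top_pathway_always_retained: bool


def prune_sweep(
    n_collections: int = 500, jaccard_max: float = 0.5, seed: int = 0
) -> PruneSweep:
    """Step-down-pruning invariants over randomized pathway collections:
    no retained pair overlaps beyond the threshold, and the most
    significant pathway always survives."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    top_ok = True
    for _ in range(n_collections):
        n_genes = int(rng.integers(20, 60))
        genes = [f"g{i:02d}" for i in range(n_genes)]
        n_path = int(rng.integers(3, 12))
        sets = {}
        for j in range(n_path):
            size = int(rng.integers(3, max(4, n_genes // 2)))
            members = frozenset(rng.choice(genes, size=size, replace=False))
            sets[f"P{j:02d}"] = (f"P{j:02d}", members)
        db = PathwayDB(sets=sets, universe=frozenset(genes))
        results = pd.DataFrame(
            {
                "pathway_id": sorted(sets),
                "pvalue": rng.random(n_path),
            }
        )
        pruned, _ = stepdown_prune(results, db, jaccard_max=jaccard_max)
        ids = list(pruned["pathway_id"])
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                worst = max(worst, jaccard(db.members(a), db.members(b)))
        best = results.sort_values(["pvalue", "pathway_id"]).iloc[0]["pathway_id"]
        top_ok &= best in ids
    return PruneSweep(
        n_collections=n_collections,
        max_retained_jaccard=worst,
        top_pathway_always_retained=top_ok,
    )
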