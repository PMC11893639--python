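"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the statistical shape of paired GWAS summary
statistics at desk scale: a large-pi0 mixture of uniform null p-values
plus a heavy left tail, with cross-study dependence concentrated among the
most significant SNPs.  Per SNP, a latent association statistic is drawn
for each study:

* null SNPs — independent standard normals in both studies;
* shared-causal SNPs — bivariate normal with mean ``noncentrality`` in both
  studies and correlation ``shared_corr``;
* study-specific causal SNPs — mean ``noncentrality`` in one study only.

Two-sided p-values and odds ratios ``exp(latent / OR_SCALE)`` (so OR > 1
iff the latent is positive) complete each record.  SNPs are placed
uniformly on a 23-chromosome map (autosomes plus X) whose lengths are the
human chromosome lengths scaled down by 100.

The same config also yields a non-overlapping gene model with exons, a
weighted planted-partition interaction network (within-community edges
denser and heavier than between), community-aligned pathway sets plus
random decoys, and a region gene list — everything the pipeline consumes,
with the ground truth (SNP causal classes, gene communities) recorded.

Shared-causal latents are built as ``z_a = nc + u`` and
``z_b = nc + rho*u + sqrt(1-rho^2)*v`` with ``u, v`` drawn in a
parameter-independent order, so runs with the same seed but different
``shared_corr`` share their random numbers — matched-seed comparisons
isolate the dependence parameter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ranklap.errors import ConfigError
from ranklap.gene_annotation import GeneModel
from ranklap.gwas_io import GwasSummary
from ranklap.network_enrichment import InteractionNetwork
from ranklap.pathway_map import PathwayDB

logger = logging.getLogger(__name__)

#: human chromosome lengths (GRCh38, Mb rounded) scaled down 100x, autosomes + X
GENOME: dict[str, int] = {
    **{
        str(i): L * 10_000
        for i, L in zip(
            range(1, 23),
            [249, 242, 198, 190, 182, 171, 159, 145, 138, 134,
             135, 133, 114, 107, 102, 90, 83, 80, 59, 64, 47, 51],
        )
    },
    "X": 156 * 10_000,
}

OR_SCALE = 10.0  # latent / OR_SCALE keeps odds ratios in a realistic band


@dataclass
class SimulationConfig:
    """All knobs of the generator, with desk-scale defaults.

    ``pi_null + pi_shared + pi_a_only + pi_b_only`` must sum to 1.
    ``noncentrality`` is the mean latent statistic of causal SNPs (standard
    normal units); ``shared_corr`` the latent correlation of shared-causal
    SNPs between the studies.
    """

    n_snps: int = 50_000
    pi_null: float = 0.97
    pi_shared: float = 0.01
    pi_a_only: float = 0.01
    pi_b_only: float = 0.01
    shared_corr: float = 0.6
    noncentrality: float = 3.0
    n_genes: int = 2_000
    n_communities: int = 4
    within_weight: float = 1.0
    between_weight: float = 0.1
    within_prob: float = 0.05
    between_prob: float = 0.005
    n_pathways: int = 20
    pathway_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.pi_null + self.pi_shared + self.pi_a_only + self.pi_b_only
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"causal-class fractions sum to {total}, not 1")
        for name in ("pi_null", "pi_shared", "pi_a_only", "pi_b_only"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} outside [0, 1]")
        if not 0 <= self.shared_corr <= 1:
            raise ConfigError("shared_corr outside [0, 1]")
        if self.noncentrality <= 0:
            raise ConfigError("noncentrality must be positive")
        for name in ("n_snps", "n_genes", "n_communities", "n_pathways", "pathway_size"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.pathway_size > self.n_genes:
            raise ConfigError("pathway_size exceeds n_genes")


@dataclass
class GroundTruth:
    """What the generator planted, for calibration and recovery tests."""

    snp_class: np.ndarray | None = None  # "null" | "shared" | "a_only" | "b_only"
    gene_community: dict[str, int] | None = None
    study_top_community: dict[str, int] | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "snp_class": None if self.snp_class is None else list(map(str, self.snp_class)),
            "gene_community": self.gene_community,
            "study_top_community": self.study_top_community,
        }
        Path(path).write_text(json.dumps(payload))


CLASSES = ("null", "shared", "a_only", "b_only")


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    from scipy import stats

    # clip away exact zeros so p stays within (0, 1]
    return np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)


def simulate_gwas_pair(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[GwasSummary, GwasSummary, GroundTruth]:
    """Paired summaries with planted tail overlap; deterministic under seed.

    The random stream is consumed in a fixed, parameter-independent order
    (positions, class labels, latent components) so matched-seed runs that
    differ only in ``shared_corr`` are coupled through common random
    numbers.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_snps

    # --- positions: uniform over the scaled genome, deterministic ids
    chrom_names = list(GENOME)
    lengths = np.array([GENOME[c] for c in chrom_names], dtype=float)
    chrom_idx = rng.choice(len(chrom_names), size=n, p=lengths / lengths.sum())
    pos = (rng.random(n) * lengths[chrom_idx]).astype(np.int64) + 1

    # --- causal classes
    probs = [cfg.pi_null, cfg.pi_shared, cfg.pi_a_only, cfg.pi_b_only]
    cls = rng.choice(4, size=n, p=probs)

    # --- latent statistics; u, v drawn for every SNP so the stream layout
    #     does not depend on the class draw or on shared_corr
    u = rng.standard_normal(n)
    v = rng.standard_normal(n)
    w_a = rng.standard_normal(n)
    w_b = rng.standard_normal(n)
    rho = cfg.shared_corr
    nc = cfg.noncentrality

    z_a = np.where(cls == 1, nc + u, np.where(cls == 2, nc + w_a, w_a))
    z_b_shared = nc + rho * u + np.sqrt(1.0 - rho**2) * v
    z_b = np.where(cls == 1, z_b_shared, np.where(cls == 3, nc + w_b, w_b))

    snp_ids = np.array([f"rs{i:08d}" for i in range(1, n + 1)])
    base = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": np.array(chrom_names, dtype=object)[chrom_idx],
            "pos": pos,
        }
    )

    def study(z: np.ndarray, label: str) -> GwasSummary:
        df = base.copy()
        df["pvalue"] = _two_sided_p(z)
        df["odds_ratio"] = np.exp(z / OR_SCALE)
        return GwasSummary(study_label=label, df=df)

    truth = GroundTruth(snp_class=np.array(CLASSES, dtype=object)[cls])
    return study(z_a, "study_a"), study(z_b, "study_b"), truth


def simulate_gene_model(
    cfg: SimulationConfig, seed: int | None = None
) -> GeneModel:
    """Non-overlapping gene spans with exons, uniform over the genome map.

    Genes are allocated to chromosomes proportionally to length, then laid
    out in disjoint slots; each gene gets 2–5 exons inside its span.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    chrom_names = list(GENOME)
    lengths = np.array([GENOME[c] for c in chrom_names], dtype=float)
    alloc = np.floor(cfg.n_genes * lengths / lengths.sum()).astype(int)
    while alloc.sum() < cfg.n_genes:  # distribute rounding remainder
        alloc[int(np.argmax(lengths / (alloc + 1)))] += 1

    rows, exons = [], {}
    gid_counter = 0
    for ci, chrom in enumerate(chrom_names):
        k = int(alloc[ci])
        if k == 0:
            continue
        slot = GENOME[chrom] // k
        if slot < 2_200:
            raise ConfigError(
                f"chromosome {chrom} too small for {k} genes (slot {slot} bp)"
            )
        for s in range(k):
            gid_counter += 1
            gid = f"G{gid_counter:05d}"
            span_len = int(rng.integers(2_000, min(8_000, slot - 100)))
            start0 = s * slot + int(rng.integers(0, slot - span_len - 1))
            end0 = start0 + span_len
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((gid, gid, chrom, start0, end0, strand))
            n_ex = int(rng.integers(2, 6))
            bounds = np.sort(rng.choice(np.arange(1, span_len), size=2 * n_ex, replace=False))
            exons[gid] = [
                (start0 + int(bounds[2 * i]), start0 + int(bounds[2 * i + 1]))
                for i in range(n_ex)
            ]
    genes = pd.DataFrame(
        rows, columns=["gene_id", "gene_symbol", "chrom", "start0", "end0", "strand"]
    )
    return GeneModel(genes=genes, exons=exons)


def _communities(cfg: SimulationConfig, gene_ids: Sequence[str]) -> dict[str, int]:
    return {g: i % cfg.n_communities for i, g in enumerate(sorted(gene_ids))}


def simulate_network(
    cfg: SimulationConfig,
    seed: int | None = None,
    gene_ids: Sequence[str] | None = None,
) -> tuple[InteractionNetwork, dict[str, int]]:
    """Weighted planted-partition network over the gene ids.

    Within-community pairs link with probability ``within_prob`` and
    exponential weights of mean ``within_weight``; between-community pairs
    with ``between_prob`` / ``between_weight``.  A zero weight parameter
    suppresses that edge class entirely, so ``between_weight = 0`` leaves
    at least ``n_communities`` connected components.
    """
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(1, cfg.n_genes + 1)]
    gene_ids = sorted(map(str, gene_ids))
    comm = _communities(cfg, gene_ids)
    labels = np.array([comm[g] for g in gene_ids])
    n = len(gene_ids)
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    prob = np.where(same, cfg.within_prob, cfg.between_prob)
    mean_w = np.where(same, cfg.within_weight, cfg.between_weight)
    present = (rng.random(len(iu)) < prob) & (mean_w > 0)
    weights = rng.exponential(np.where(mean_w > 0, mean_w, 1.0))[present]
    edges = [
        (gene_ids[a], gene_ids[b], float(w))
        for a, b, w in zip(iu[present], ju[present], weights)
    ]
    if not edges:
        raise ConfigError("simulated network has no edges; raise the edge probabilities")
    return InteractionNetwork(edges), comm


def simulate_pathways(
    cfg: SimulationConfig,
    communities: dict[str, int],
    seed: int | None = None,
) -> PathwayDB:
    """Community-aligned pathways plus random decoys; universe = all genes.

    The first ``n_communities`` pathways sample their members from one
    community each; the remainder are uniform decoys.
    """
    rng = np.random.default_rng(cfg.seed + 3 if seed is None else seed)
    genes = sorted(communities)
    by_comm: dict[int, list[str]] = {}
    for g in genes:
        by_comm.setdefault(communities[g], []).append(g)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for k in range(cfg.n_pathways):
        pid = f"PW{k + 1:04d}"
        if k < cfg.n_communities:
            pool = by_comm[k]
            name = f"community_{k}_pathway"
        else:
            pool = genes
            name = f"decoy_pathway_{k}"
        size = min(cfg.pathway_size, len(pool))
        members = rng.choice(pool, size=size, replace=False)
        sets[pid] = (name, frozenset(map(str, members)))
    return PathwayDB(sets=sets, universe=frozenset(genes))


def simulate_region_genes(
    communities: dict[str, int], community: int = 0, k: int = 47, seed: int = 0
) -> list[str]:
    """A fixed region gene list: k genes sampled from one community (the
    stand-in for a microdeletion-region gene set)."""
    pool = sorted(g for g, c in communities.items() if c == community)
    rng = np.random.default_rng(seed)
    return sorted(rng.choice(pool, size=min(k, len(pool)), replace=False))


def generate_all(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit every pipeline input under ``outdir`` plus a ground-truth JSON.

    Files: gwas_a.tsv, gwas_b.tsv, genes.bed, network.tsv, pathways.gmt,
    region_genes.txt, ground_truth.json.
    """
    from ranklap.gene_annotation import write_gene_model_bed
    from ranklap.gwas_io import write_gwas_summary
    from ranklap.network_enrichment import write_network
    from ranklap.pathway_map import write_gmt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    a, b, truth = simulate_gwas_pair(cfg)
    model = simulate_gene_model(cfg)
    network, comm = simulate_network(cfg, gene_ids=list(model.genes["gene_id"]))
    db = simulate_pathways(cfg, comm)
    region = simulate_region_genes(comm, seed=cfg.seed + 4)
    truth.gene_community = comm

    paths = {
        "gwas_a": outdir / "gwas_a.tsv",
        "gwas_b": outdir / "gwas_b.tsv",
        "genes": outdir / "genes.bed",
        "network": outdir / "network.tsv",
        "pathways": outdir / "pathways.gmt",
        "region_genes": outdir / "region_genes.txt",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_gwas_summary(a, paths["gwas_a"])
    write_gwas_summary(b, paths["gwas_b"])
    write_gene_model_bed(model, paths["genes"])
    write_network(network, paths["network"])
    write_gmt(db, paths["pathways"])
    paths["region_genes"].write_text("\n".join(region) + "\n")
    truth.to_json(paths["ground_truth"])
    logger.info("synthetic inputs written to %s", outdir)
    return paths
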