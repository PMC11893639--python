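"""Gene-network overlap: interaction scoring, query expansion, preranked GSEA.

The second analysis stage asks whether two studies' top genes occupy the
same neighborhood of a weighted, undirected gene-interaction network.  One
study's top genes form the *reference set*: every network gene outside the
set receives an interaction score equal to its summed edge weight into the
set, and reference genes themselves are pinned to the maximum
non-reference score so they occupy the top of the ranking.  The other
study's top genes form the *query seed*, greedily expanded one gene at a
time through the network (always adding the non-member with the largest
summed edge weight into the current set) with snapshots at sizes
100, 200, ..., 1000.

Each snapshot is tested for enrichment near the top of the
interaction-score ranking with the classic weighted Kolmogorov–Smirnov
running-sum statistic of preranked GSEA; the null is gene-label
permutation (random sets of the same size).  Benjamini–Hochberg adjustment
is applied across the family of expansion sizes, and a size is flagged
significant when its adjusted p is below alpha *and* its enrichment score
is positive (overlap, not depletion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from statsmodels.stats.multitest import multipletests

from ranklap.errors import ConfigError, InputError
from ranklap.gene_annotation import TopGeneList
from ranklap.rank_overlap import CrossTableResult, PairedRanks

logger = logging.getLogger(__name__)

DEFAULT_SIZES = tuple(range(100, 1001, 100))
DEFAULT_GSEA_PERM = 1000
#: tolerance for resolving positive/negative extreme ties in the running sum
ES_TIE_TOL = 1e-9


class InteractionNetwork:
    """Undirected weighted gene network backed by a sparse adjacency matrix.

    Nodes are kept sorted by gene id so argmax tie-breaks are
    lexicographic.  Self-loops are rejected; edge weights must be finite
    and non-negative.
    """

    def __init__(self, edges: Iterable[tuple[str, str, float]]):
        edge_list = [(str(a), str(b), float(w)) for a, b, w in edges]
        for a, b, w in edge_list:
            if a == b:
                raise InputError(f"self-loop on {a!r}")
            if not np.isfinite(w) or w < 0:
                raise InputError(f"bad edge weight {w!r} on {a}-{b}")
        nodes = sorted({g for a, b, _ in edge_list for g in (a, b)})
        if not nodes:
            raise InputError("network has no edges")
        self.nodes: list[str] = nodes
        self.index: dict[str, int] = {g: i for i, g in enumerate(nodes)}
        n = len(nodes)
        ii = [self.index[a] for a, _, _ in edge_list]
        jj = [self.index[b] for _, b, _ in edge_list]
        ww = [w for _, _, w in edge_list]
        m = sparse.coo_matrix((ww + ww, (ii + jj, jj + ii)), shape=(n, n))
        # duplicate edges sum; symmetric by construction
        self.adjacency: sparse.csr_matrix = m.tocsr()

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        coo = sparse.triu(self.adjacency, k=1).tocoo()
        g.add_weighted_edges_from(
            (self.nodes[i], self.nodes[j], float(w))
            for i, j, w in zip(coo.row, coo.col, coo.data)
        )
        return g

    def member_indices(self, genes: Iterable[str], what: str = "genes") -> np.ndarray:
        present, absent = [], []
        for g in genes:
            (present if g in self.index else absent).append(g)
        if absent:
            logger.warning("%d %s absent from network (ignored)", len(absent), what)
        return np.array([self.index[g] for g in present], dtype=np.int64)


def read_network(path: str | Path) -> InteractionNetwork:
    """Read a 3-column TSV edge list (gene_a, gene_b, weight); a header
    line is detected by a non-numeric third field."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"network file not found: {path}")
    edges = []
    for k, line in enumerate(path.read_text().splitlines()):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 3:
            raise InputError(f"{path.name} line {k + 1}: need 3 columns")
        try:
            w = float(f[2])
        except ValueError:
            if k == 0:
                continue  # header
            raise InputError(f"{path.name} line {k + 1}: bad weight {f[2]!r}")
        edges.append((f[0], f[1], w))
    return InteractionNetwork(edges)


def write_network(network: InteractionNetwork, path: str | Path) -> None:
    coo = sparse.triu(network.adjacency, k=1).tocoo()
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for i, j, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{network.nodes[i]}\t{network.nodes[j]}\t{w:g}\n")


@dataclass
class ScoredGeneList:
    """All network genes ranked by interaction score against a reference set.

    ``df`` columns: gene_id, score — descending score, ties by gene_id.
    Reference genes all carry the maximum non-reference score, so they sit
    in the top block of the ranking.
    """

    df: pd.DataFrame = field(repr=False)
    reference: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.df)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.df["gene_id"].to_numpy()

    @property
    def scores(self) -> np.ndarray:
        return self.df["score"].to_numpy(dtype=float)


def _as_gene_ids(genes) -> list[str]:
    if isinstance(genes, TopGeneList):
        return genes.gene_ids
    return list(genes)


def score_against_reference(
    network: InteractionNetwork, reference
) -> ScoredGeneList:
    """Interaction score = summed edge weight into the reference set.

    Reference genes present in the network are pinned to the maximum
    non-reference score; reference genes absent from the network are
    logged and ignored.
    """
    ref_ids = _as_gene_ids(reference)
    ref_idx = network.member_indices(ref_ids, "reference genes")
    if len(ref_idx) == 0:
        raise InputError("no reference gene is present in the network")
    indicator = np.zeros(len(network))
    indicator[ref_idx] = 1.0
    scores = network.adjacency @ indicator
    non_ref = np.ones(len(network), dtype=bool)
    non_ref[ref_idx] = False
    max_non_ref = float(scores[non_ref].max()) if non_ref.any() else 0.0
    scores[ref_idx] = max_non_ref
    df = pd.DataFrame({"gene_id": network.nodes, "score": scores})
    order = np.lexsort((df["gene_id"].to_numpy(), -df["score"].to_numpy()))
    return ScoredGeneList(
        df=df.iloc[order].reset_index(drop=True),
        reference=frozenset(network.nodes[i] for i in ref_idx),
    )


def expand_query(
    network: InteractionNetwork,
    query_seed,
    sizes: Sequence[int] = DEFAULT_SIZES,
) -> dict[int, frozenset[str]]:
    """Greedy query-set expansion with snapshots at the requested sizes.

    Starting from the seed genes present in the network, repeatedly add the
    non-member gene with the largest summed edge weight into the current
    set (ties broken by gene id).  Sets are nested by construction; sizes
    beyond the network order are dropped with a warning.
    """
    sizes = sorted(set(int(s) for s in sizes))
    if not sizes or sizes[0] < 1:
        raise ConfigError("expansion sizes must be positive")
    seed_idx = network.member_indices(_as_gene_ids(query_seed), "query seed genes")
    if len(seed_idx) == 0:
        raise InputError("no query seed gene is present in the network")
    n = len(network)
    if sizes[-1] >= n:
        logger.warning(
            "network has %d genes; truncating expansion sizes beyond %d", n, n - 1
        )
        sizes = [s for s in sizes if s < n]
        if not sizes:
            raise InputError("network smaller than every requested size")

    member = np.zeros(n, dtype=bool)
    member[seed_idx] = True
    # summed weight of every node into the current member set
    attachment = np.asarray(
        network.adjacency @ member.astype(float)
    ).ravel()
    snapshots: dict[int, frozenset[str]] = {}
    adj = network.adjacency
    target = sizes[-1]
    size_iter = iter(sizes)
    next_size = next(size_iter)
    current = int(member.sum())
    while True:
        while next_size is not None and current >= next_size:
            snapshots[next_size] = frozenset(
                network.nodes[i] for i in np.flatnonzero(member)
            )
            next_size = next(size_iter, None)
        if next_size is None or current >= target:
            break
        masked = np.where(member, -np.inf, attachment)
        pick = int(np.argmax(masked))  # first max = smallest gene id
        if masked[pick] <= 0:
            logger.warning(
                "expansion exhausted at %d genes: no remaining gene attaches "
                "to the current set", current,
            )
            break
        member[pick] = True
        current += 1
        row = adj.getrow(pick)
        attachment[row.indices] += row.data
    return snapshots


@dataclass
class GseaResult:
    es: float
    nes: float
    pvalue: float
    n_hits: int
    n_perm: int
    seed: int | None


def _running_es(
    hit_pos: np.ndarray, weights: np.ndarray, n_total: int
) -> float:
    """Signed maximum deviation of the weighted KS running sum.

    ``hit_pos`` are sorted 0-based positions of the gene set in the ranked
    list; ``weights`` the |score|^exponent at those positions.  Hits
    increment by weight / total weight (equal weights when the total is
    zero); misses decrement by 1/(N - n_hits).  Extremes occur at hit
    boundaries, so only those points are evaluated.
    """
    nh = len(hit_pos)
    total = weights.sum()
    if total > 0:
        cum = np.cumsum(weights) / total
    else:  # degenerate all-zero weights: fall back to equal increments
        cum = np.arange(1, nh + 1) / nh
    miss_denom = n_total - nh
    j = np.arange(nh)
    if miss_denom == 0:
        raise InputError("gene set must be a proper subset of the ranked list")
    after = cum - (hit_pos + 1 - (j + 1)) / miss_denom
    before = np.concatenate(([0.0], cum[:-1])) - (hit_pos - j) / miss_denom
    hi = after.max()
    lo = before.min()
    # ties between the positive and negative extreme resolve positive;
    # the 1e-9 slack keeps the choice stable under float round-off
    return float(hi if hi >= -lo - ES_TIE_TOL else lo)


def _batch_null_es(
    scores_pow: np.ndarray, n_hits: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """ES for ``n_perm`` random gene sets of size ``n_hits`` (vectorized)."""
    n = len(scores_pow)
    # random hit positions per permutation, sorted along rows
    pos = np.empty((n_perm, n_hits), dtype=np.int64)
    for k in range(n_perm):
        pos[k] = rng.choice(n, size=n_hits, replace=False)
    pos.sort(axis=1)
    w = scores_pow[pos]
    total = w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cum = np.where(total > 0, cum / np.where(total == 0, 1.0, total),
                       np.arange(1, n_hits + 1) / n_hits)
    j = np.arange(n_hits)
    miss_denom = n - n_hits
    after = cum - (pos + 1 - (j + 1)) / miss_denom
    before = np.concatenate(
        [np.zeros((n_perm, 1)), cum[:, :-1]], axis=1
    ) - (pos - j) / miss_denom
    hi = after.max(axis=1)
    lo = before.min(axis=1)
    return np.where(hi >= -lo - ES_TIE_TOL, hi, lo)


def gsea_preranked(
    ranked: ScoredGeneList,
    gene_set: Iterable[str],
    weight_exponent: float = 1.0,
    n_perm: int = DEFAULT_GSEA_PERM,
    seed: int | None = 0,
) -> GseaResult:
    """Preranked GSEA of one gene set against an interaction-score ranking.

    ES is the signed maximum deviation of the weighted running sum; the
    null is gene-label permutation (random sets of equal size).  NES is ES
    divided by the mean same-sign permuted ES, and the nominal p is the
    add-one fraction of same-sign permuted ES at least as extreme.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    genes = ranked.gene_ids
    gene_set = frozenset(gene_set)
    hit_mask = np.isin(genes, list(gene_set))
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise InputError("gene set does not intersect the ranked list")
    if n_hits == len(genes):
        raise InputError("gene set must be a proper subset of the ranked list")
    scores_pow = np.abs(ranked.scores) ** weight_exponent
    hit_pos = np.flatnonzero(hit_mask)
    es = _running_es(hit_pos, scores_pow[hit_pos], len(genes))

    rng = np.random.default_rng(seed)
    null = _batch_null_es(scores_pow, n_hits, n_perm, rng)
    same_sign = null >= 0 if es >= 0 else null < 0
    null_ss = np.abs(null[same_sign])
    if len(null_ss) == 0:
        nes = np.nan
        pvalue = 1.0 / (n_perm + 1)
    else:
        mean_ss = null_ss.mean()
        nes = float(np.sign(es) * abs(es) / mean_ss) if mean_ss > 0 else np.nan
        pvalue = (1 + int((null_ss >= abs(es)).sum())) / (len(null_ss) + 1)
    return GseaResult(
        es=es, nes=nes, pvalue=float(pvalue), n_hits=n_hits, n_perm=n_perm, seed=seed
    )


@dataclass
class ExpansionProfile:
    """Per-expansion-size enrichment results with BH-adjusted p-values.

    ``df`` columns: size, n_set, es, nes, pvalue, p_adjusted, significant.
    ``significant`` requires ES > 0 (overlap, not depletion) and adjusted
    p < alpha.
    """

    reference_label: str
    query_label: str
    df: pd.DataFrame = field(repr=False)
    sets: dict[int, frozenset[str]] = field(default_factory=dict, repr=False)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @property
    def significant_sizes(self) -> list[int]:
        return list(self.df.loc[self.df["significant"], "size"])


def overlap_profile(
    network: InteractionNetwork,
    reference,
    query_seed,
    sizes: Sequence[int] = DEFAULT_SIZES,
    weight_exponent: float = 1.0,
    n_perm: int = DEFAULT_GSEA_PERM,
    seed: int | None = 0,
    alpha: float = 0.05,
    reference_label: str = "reference",
    query_label: str = "query",
) -> ExpansionProfile:
    """Full network-overlap profile of a query study against a reference.

    Scores the network against the reference genes, greedily expands the
    query seed, runs preranked GSEA at every snapshot size, and adjusts the
    nominal p-values with Benjamini–Hochberg across the size family.
    """
    ranked = score_against_reference(network, reference)
    snapshots = expand_query(network, query_seed, sizes)
    rows = []
    rng = np.random.default_rng(seed)
    for size in sorted(snapshots):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = gsea_preranked(
            ranked,
            snapshots[size],
            weight_exponent=weight_exponent,
            n_perm=n_perm,
            seed=sub_seed,
        )
        rows.append((size, len(snapshots[size]), res.es, res.nes, res.pvalue))
    df = pd.DataFrame(rows, columns=["size", "n_set", "es", "nes", "pvalue"])
    _, p_adj, _, _ = multipletests(df["pvalue"], method="fdr_bh")
    df["p_adjusted"] = p_adj
    df["significant"] = (df["es"] > 0) & (df["p_adjusted"] < alpha)
    return ExpansionProfile(
        reference_label=reference_label,
        query_label=query_label,
        df=df,
        sets=snapshots,
    )


def region_comparison(
    network: InteractionNetwork,
    region_genes: Iterable[str],
    study_top,
    sizes: Sequence[int] = DEFAULT_SIZES,
    **kwargs,
) -> ExpansionProfile:
    """Network-overlap profile of a study against a fixed region gene list
    (e.g. the genes within a recurrent microdeletion region): identical
    machinery with the region list as the reference set."""
    region_genes = list(region_genes)
    if not region_genes:
        raise InputError("region gene list is empty")
    kwargs.setdefault("reference_label", "region")
    return overlap_profile(network, region_genes, study_top, sizes=sizes, **kwargs)


def region_snp_fraction(
    result: CrossTableResult,
    pairs: PairedRanks,
    region: tuple[str, int, int],
) -> float | None:
    """Percentage of significant-cell SNPs lying inside a genomic region.

    ``region`` is (chrom, start, end), 1-based inclusive.  Returns None
    when no cells were called significant (the quantity is undefined).
    """
    cells = result.significant_cells
    if len(cells) == 0:
        logger.warning("no significant cells: region SNP fraction undefined")
        return None
    if pairs.chrom is None or pairs.pos is None:
        raise InputError("paired ranks carry no SNP coordinates")
    cell_set = set(zip(cells["bin_a"], cells["bin_b"]))
    in_cell = np.array(
        [(a, b) in cell_set for a, b in zip(pairs.bin_a, pairs.bin_b)]
    )
    chrom, start, end = region
    in_region = (
        (pairs.chrom == str(chrom)) & (pairs.pos >= int(start)) & (pairs.pos <= int(end))
    )
    total = int(in_cell.sum())
    return 100.0 * int((in_cell & in_region).sum()) / total


def export_profile_heatmap(
    profiles: Sequence[ExpansionProfile], path: str | Path, alpha: float = 0.05
) -> None:
    """Significance-profile strip chart: one row per (reference, query)
    pair, one cell per expansion size, red when flagged significant."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    sizes = sorted({int(s) for p in profiles for s in p.df["size"]})
    mat = np.zeros((len(profiles), len(sizes)))
    labels = []
    for r, prof in enumerate(profiles):
        labels.append(f"{prof.reference_label} vs {prof.query_label}")
        flagged = dict(zip(prof.df["size"], prof.df["significant"]))
        for c, s in enumerate(sizes):
            mat[r, c] = 1.0 if flagged.get(s, False) else 0.0
    fig, ax = plt.subplots(figsize=(8, 1 + 0.6 * len(profiles)))
    ax.imshow(mat, cmap=ListedColormap(["#d9d9d9", "#d62728"]), vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(len(sizes)), [str(s) for s in sizes])
    ax.set_yticks(range(len(labels)), labels)
    ax.set_xlabel("expanded query-set size")
    ax.set_title(f"network overlap significance (adjusted p < {alpha:g}, ES > 0)")
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)
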