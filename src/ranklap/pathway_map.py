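"""Pathway enrichment, enrichment-map graphs, and redundancy pruning.

Gene sets implicated by the earlier stages are tested against a local
pathway database (GMT) with the one-sided hypergeometric test: the p-value
for a pathway with K members in a universe of M genes, given a query of n
genes overlapping it in k, is P(X >= k) for X hypergeometric(M, K, n).
Benjamini–Hochberg adjustment is applied across pathways and a
conservative adjusted-p threshold (default 5e-5) defines significance.

Significant pathways become nodes of an *enrichment map*: edges join
pathway pairs whose gene memberships overlap with Jaccard index >= 0.35
(boundary inclusive), and a step-down pruning pass walks pathways by
ascending p, discarding any pathway whose Jaccard with an already-retained
pathway exceeds 0.5 — keeping the map sparse while always retaining the
most significant representative of each redundant cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ranklap.errors import ConfigError, InputError
from ranklap.network_enrichment import ScoredGeneList

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_ADJ = 5e-5
DEFAULT_EDGE_MIN = 0.35
DEFAULT_PRUNE_MAX = 0.5


@dataclass
class PathwayDB:
    """Named gene sets plus the background gene universe.

    ``sets`` maps pathway_id -> (name, frozenset of member gene ids); the
    universe defaults to the union of all members but is normally the full
    gene complement of the organism/model.
    """

    sets: dict[str, tuple[str, frozenset[str]]] = field(repr=False)
    universe: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.sets:
            raise InputError("pathway database is empty")
        members = frozenset().union(*(m for _, m in self.sets.values()))
        if not self.universe:
            self.universe = members
        elif not members <= self.universe:
            raise InputError("pathway members outside the declared universe")
        if any(len(m) == 0 for _, m in self.sets.values()):
            raise InputError("empty pathway in database")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, pathway_id: str) -> frozenset[str]:
        return self.sets[pathway_id][1]


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> PathwayDB:
    """Read a GMT file: one pathway per line, tab-delimited
    ``id <tab> description <tab> gene1 <tab> gene2 ...``."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"GMT file not found: {path}")
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for k, line in enumerate(path.read_text().splitlines()):
        if not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 3:
            raise InputError(f"{path.name} line {k + 1}: need id, description, genes")
        sets[f[0]] = (f[1], frozenset(g for g in f[2:] if g))
    return PathwayDB(sets=sets, universe=frozenset(universe) if universe else frozenset())


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, (name, members) in db.sets.items():
            fh.write("\t".join([pid, name, *sorted(members)]) + "\n")


def jaccard(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """Jaccard index |A∩B| / |A∪B|; undefined (error) when both are empty."""
    a, b = frozenset(set_a), frozenset(set_b)
    union = a | b
    if not union:
        raise InputError("Jaccard undefined for two empty sets")
    return len(a & b) / len(union)


def enrich(
    query_genes: Iterable[str],
    db: PathwayDB,
    alpha_adj: float = DEFAULT_ALPHA_ADJ,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a query gene set against every pathway.

    Query genes outside the universe are dropped (logged).  Returns one row
    per pathway with columns ``pathway_id, name, k, K, n, M, pvalue,
    p_adjusted, significant``, sorted by ascending p then pathway_id.
    """
    query = frozenset(query_genes)
    inside = query & db.universe
    dropped = len(query) - len(inside)
    if dropped:
        logger.warning("%d query genes outside the universe dropped", dropped)
    if not inside:
        raise InputError("no query gene lies in the pathway universe")
    M, n = len(db.universe), len(inside)
    rows = []
    for pid in sorted(db.sets):
        name, members = db.sets[pid]
        K = len(members)
        k = len(inside & members)
        # P(X >= k), X ~ Hypergeom(M, K, n); k = 0 gives p = 1
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append((pid, name, k, K, n, M, min(p, 1.0)))
    df = pd.DataFrame(
        rows, columns=["pathway_id", "name", "k", "K", "n", "M", "pvalue"]
    )
    _, p_adj, _, _ = multipletests(df["pvalue"], method="fdr_bh")
    df["p_adjusted"] = p_adj
    df["significant"] = df["p_adjusted"] < alpha_adj
    return df.sort_values(["pvalue", "pathway_id"], kind="mergesort").reset_index(
        drop=True
    )


def stepdown_prune(
    results: pd.DataFrame,
    db: PathwayDB,
    jaccard_max: float = DEFAULT_PRUNE_MAX,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Greedy redundancy pruning by ascending p-value.

    Walking pathways from most to least significant (ties by pathway_id),
    a pathway is retained iff its Jaccard with every already-retained
    pathway is <= ``jaccard_max`` (strictly-greater overlaps are
    discarded).  Returns the retained rows and a log of
    (discarded_id, retained_representative_id) pairs.
    """
    ordered = results.sort_values(
        ["pvalue", "pathway_id"], kind="mergesort"
    ).reset_index(drop=True)
    retained: list[str] = []
    log: list[tuple[str, str]] = []
    for row in ordered.itertuples(index=False):
        members = db.members(row.pathway_id)
        clash = next(
            (r for r in retained if jaccard(members, db.members(r)) > jaccard_max),
            None,
        )
        if clash is None:
            retained.append(row.pathway_id)
        else:
            log.append((row.pathway_id, clash))
    pruned = ordered[ordered["pathway_id"].isin(retained)].reset_index(drop=True)
    return pruned, log


def build_map(
    results_by_cohort: Mapping[str, pd.DataFrame],
    db: PathwayDB,
    edge_min: float = DEFAULT_EDGE_MIN,
) -> nx.Graph:
    """Enrichment-map graph over the significant pathways of all cohorts.

    Nodes are the union of significant pathways with per-cohort tags and
    the smallest p across cohorts; edges join pairs with Jaccard >=
    ``edge_min`` (boundary inclusive).  The edge set is invariant to node
    input order.
    """
    nodes: dict[str, dict] = {}
    for cohort, df in results_by_cohort.items():
        sig = df[df["significant"]]
        for row in sig.itertuples(index=False):
            d = nodes.setdefault(
                row.pathway_id,
                {"name": row.name, "pvalue": float(row.pvalue), "cohorts": set()},
            )
            d["cohorts"].add(cohort)
            d["pvalue"] = min(d["pvalue"], float(row.pvalue))
    if not nodes:
        raise InputError("no significant pathway in any cohort")
    g = nx.Graph()
    for pid in sorted(nodes):
        d = nodes[pid]
        g.add_node(
            pid, name=d["name"], pvalue=d["pvalue"], cohorts=",".join(sorted(d["cohorts"]))
        )
    ids = sorted(nodes)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            jac = jaccard(db.members(a), db.members(b))
            if jac >= edge_min:
                g.add_edge(a, b, jaccard=jac)
    return g


def export_map(graph: nx.Graph, outdir: str | Path, basename: str = "enrichment_map") -> dict[str, Path]:
    """Write the enrichment map as GraphML plus node/edge TSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "graphml": outdir / f"{basename}.graphml",
        "nodes": outdir / f"{basename}_nodes.tsv",
        "edges": outdir / f"{basename}_edges.tsv",
    }
    nx.write_graphml(graph, paths["graphml"])
    pd.DataFrame(
        [
            {"pathway_id": n, **graph.nodes[n]}
            for n in sorted(graph.nodes)
        ]
    ).to_csv(paths["nodes"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"pathway_a": a, "pathway_b": b, "jaccard": d["jaccard"]}
            for a, b, d in sorted(graph.edges(data=True))
        ],
        columns=["pathway_a", "pathway_b", "jaccard"],
    ).to_csv(paths["edges"], sep="\t", index=False)
    return paths


def driver_subset(scored: ScoredGeneList) -> frozenset[str]:
    """Genes with interaction score strictly above the mean of all scores —
    the subset that drives enrichment in the network stage."""
    if len(scored) == 0:
        raise InputError("empty scored gene list")
    scores = scored.scores
    mean = scores.mean()
    return frozenset(scored.gene_ids[scores > mean])


def overlap_pathway_comparison(
    gene_lists: Mapping[str, Iterable[str]],
    db: PathwayDB,
    alpha_adj: float = DEFAULT_ALPHA_ADJ,
) -> pd.DataFrame:
    """Pairwise Jaccard matrix of the significant-pathway sets of each list.

    Each named gene list is enriched independently; the Jaccard index is
    computed between the significant pathway-ID sets of every pair.  The
    diagonal is 1 where a list has at least one significant pathway and NaN
    otherwise (Jaccard of two empty sets is undefined).
    """
    names = list(gene_lists)
    if len(names) < 2:
        raise ConfigError("need at least two named gene lists")
    sig_sets = {}
    for name in names:
        res = enrich(gene_lists[name], db, alpha_adj=alpha_adj)
        sig_sets[name] = frozenset(res.loc[res["significant"], "pathway_id"])
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            if not (sig_sets[a] | sig_sets[b]):
                mat.loc[a, b] = float("nan")
            else:
                mat.loc[a, b] = jaccard(sig_sets[a], sig_sets[b])
    return mat
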