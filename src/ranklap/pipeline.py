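"""End-to-end orchestration: simulate/ingest -> SNP overlap -> annotation ->
network enrichment -> pathway map, from a single validated config.

A run is fully described by a :class:`RunConfig` (YAML on disk), executes
its five stages in order under one output directory, and emits a
:class:`RunManifest` with the config echo, software version, per-stage
wall-clock, warnings, and a SHA-256 checksum of every written file —
enough to verify bit-identical re-runs under the same seed.

A single top-level seed deterministically derives independent per-stage
streams, so stages are reproducible standalone as well.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from ranklap import __version__
from ranklap.errors import ConfigError, InputError
from ranklap import gwas_io, rank_overlap, gene_annotation, network_enrichment, pathway_map
from ranklap.synthetic import SimulationConfig

logger = logging.getLogger(__name__)

STAGES = ("inputs", "snp_overlap", "annotation", "network", "pathways")

DEFAULT_COLUMN_MAP = {
    "snp_id": "snp_id",
    "chrom": "chrom",
    "pos": "pos",
    "pvalue": "pvalue",
    "odds_ratio": "odds_ratio",
}


class InputPaths(BaseModel):
    model_config = ConfigDict(extra="forbid")
    gwas_a: str
    gwas_b: str
    gene_model: str
    network: str
    pathways: str
    region_genes: Optional[str] = None
    column_map: dict[str, str] = Field(default_factory=lambda: dict(DEFAULT_COLUMN_MAP))


class SimulateSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_snps: int = Field(50_000, ge=100)
    pi_null: float = Field(0.97, ge=0, le=1)
    pi_shared: float = Field(0.01, ge=0, le=1)
    pi_a_only: float = Field(0.01, ge=0, le=1)
    pi_b_only: float = Field(0.01, ge=0, le=1)
    shared_corr: float = Field(0.6, ge=0, le=1)
    noncentrality: float = Field(3.0, gt=0)
    n_genes: int = Field(2_000, ge=1)
    n_communities: int = Field(4, ge=1)
    within_weight: float = Field(1.0, ge=0)
    between_weight: float = Field(0.1, ge=0)
    within_prob: float = Field(0.05, ge=0, le=1)
    between_prob: float = Field(0.005, ge=0, le=1)
    n_pathways: int = Field(20, ge=1)
    pathway_size: int = Field(100, ge=1)

    @model_validator(mode="after")
    def _fractions(self):
        if abs(self.pi_null + self.pi_shared + self.pi_a_only + self.pi_b_only - 1) > 1e-9:
            raise ValueError("pi_null + pi_shared + pi_a_only + pi_b_only must equal 1")
        return self


class RegionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    chrom: str
    start: int = Field(ge=1)
    end: int = Field(ge=1)

    @model_validator(mode="after")
    def _span(self):
        if self.end < self.start:
            raise ValueError("region end before start")
        return self


class RunConfig(BaseModel):
    """Validated parameters of a full run; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "ranklap_run"
    inputs: Optional[InputPaths] = None
    simulate: Optional[SimulateSection] = None

    bins: int = Field(30, ge=2)
    z_threshold: float = Field(4.0, gt=0)
    alpha: float = Field(0.05, gt=0, le=1)
    n_perm: int = Field(20_000, ge=1)
    perm_statistic: str = Field("max_quadrant_z", pattern="^(max_quadrant_z|quadrant_exceedance)$")

    window: int = Field(1_000, ge=0)
    k_top: int = Field(100, ge=1)

    sizes: list[int] = Field(default_factory=lambda: list(range(100, 1001, 100)))
    n_perm_gsea: int = Field(1_000, ge=1)
    weight_exponent: float = Field(1.0, ge=0)

    alpha_adj: float = Field(5e-5, gt=0, le=1)
    edge_min: float = Field(0.35, ge=0, le=1)
    prune_max: float = Field(0.5, ge=0, le=1)
    region: Optional[RegionSection] = None

    @model_validator(mode="after")
    def _one_source(self):
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("exactly one of 'inputs' or 'simulate' must be given")
        if any(s < 1 for s in self.sizes):
            raise ValueError("expansion sizes must be positive")
        return self


def validate_config(path: str | Path) -> RunConfig:
    """Load and fully validate a YAML run config; all schema violations are
    reported together in the raised ConfigError."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(f"{path}: invalid config:\n" + "\n".join(lines)) from exc


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: list[str] = field(default_factory=list)
    wall_clock: dict[str, float] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config": self.config,
                    "version": self.version,
                    "stages": self.stages,
                    "wall_clock": self.wall_clock,
                    "checksums": self.checksums,
                    "warnings": self.warnings,
                },
                indent=2,
                sort_keys=True,
            )
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage stream from the top-level seed, below 2**31."""
    return int(
        np.random.SeedSequence([seed, STAGES.index(stage)]).generate_state(1)[0]
        % (2**31 - 1)
    )


class _ManifestWarnings(logging.Handler):
    def __init__(self, sink: list[str]):
        super().__init__(level=logging.WARNING)
        self.sink = sink

    def emit(self, record):
        self.sink.append(self.format(record))


def run_full(config: RunConfig) -> RunManifest:
    """Execute every stage under ``config.out_dir``; returns the manifest.

    Any stage failure raises with a stage-tagged message; outputs written
    before the failure are retained for debugging.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=json.loads(config.model_dump_json()), version=__version__)
    collector = _ManifestWarnings(manifest.warnings)
    logging.getLogger("ranklap").addHandler(collector)
    stage = "inputs"
    try:
        # ---------------------------------------------------------- inputs
        t0 = time.perf_counter()
        if config.simulate is not None:
            sim_cfg = SimulationConfig(
                **config.simulate.model_dump(), seed=_stage_seed(config.seed, "inputs")
            )
            from ranklap.synthetic import generate_all

            paths = generate_all(sim_cfg, out / "inputs")
            column_map = dict(DEFAULT_COLUMN_MAP)
            region_genes_path = paths["region_genes"]
            gwas_a_path, gwas_b_path = paths["gwas_a"], paths["gwas_b"]
            gene_model_path, network_path, gmt_path = (
                paths["genes"], paths["network"], paths["pathways"],
            )
        else:
            inp = config.inputs
            column_map = inp.column_map
            gwas_a_path, gwas_b_path = Path(inp.gwas_a), Path(inp.gwas_b)
            gene_model_path, network_path, gmt_path = (
                Path(inp.gene_model), Path(inp.network), Path(inp.pathways),
            )
            region_genes_path = Path(inp.region_genes) if inp.region_genes else None

        a = gwas_io.read_gwas_summary(gwas_a_path, column_map, "study_a")
        b = gwas_io.read_gwas_summary(gwas_b_path, column_map, "study_b")
        model = gene_annotation.read_gene_model(gene_model_path)
        network = network_enrichment.read_network(network_path)
        db = pathway_map.read_gmt(gmt_path)
        region_genes = (
            gene_annotation.read_gene_list(region_genes_path) if region_genes_path else None
        )
        manifest.wall_clock[stage] = time.perf_counter() - t0
        manifest.stages.append(stage)

        # ----------------------------------------------------- snp_overlap
        stage = "snp_overlap"
        t0 = time.perf_counter()
        table = gwas_io.intersect_studies(a, b)
        result, pairs = rank_overlap.analyze_pair(
            table,
            n_bins=config.bins,
            z_threshold=config.z_threshold,
            alpha=config.alpha,
            n_perm=config.n_perm,
            seed=_stage_seed(config.seed, "snp_overlap"),
            statistic=config.perm_statistic,
        )
        stage_dir = out / "snp_overlap"
        rank_overlap.export_heatmap(result, stage_dir)
        table.to_tsv(stage_dir / "paired_snps.tsv")
        manifest.wall_clock[stage] = time.perf_counter() - t0
        manifest.stages.append(stage)

        # ------------------------------------------------------ annotation
        stage = "annotation"
        t0 = time.perf_counter()
        stage_dir = out / "annotation"
        stage_dir.mkdir(exist_ok=True)
        tops: dict[str, gene_annotation.TopGeneList] = {}
        for summary in (a, b):
            filtered = gwas_io.filter_for_gene_selection(summary)
            ann = gene_annotation.annotate(filtered, model, window=config.window)
            tops[summary.study_label] = gene_annotation.select_top_genes(
                filtered, ann, k=config.k_top
            )
            ann.to_tsv(stage_dir / f"{summary.study_label}_annotations.tsv")
            gene_annotation.snp_type_proportions(ann).to_csv(
                stage_dir / f"{summary.study_label}_snp_type_proportions.tsv",
                sep="\t", index=False,
            )
            tops[summary.study_label].to_tsv(
                stage_dir / f"{summary.study_label}_top_genes.tsv"
            )
        manifest.wall_clock[stage] = time.perf_counter() - t0
        manifest.stages.append(stage)

        # --------------------------------------------------------- network
        stage = "network"
        t0 = time.perf_counter()
        stage_dir = out / "network"
        stage_dir.mkdir(exist_ok=True)
        net_seed = _stage_seed(config.seed, "network")
        top_a, top_b = tops["study_a"], tops["study_b"]
        profiles = []
        for ref, qry in ((top_a, top_b), (top_b, top_a)):
            prof = network_enrichment.overlap_profile(
                network, ref, qry,
                sizes=config.sizes,
                weight_exponent=config.weight_exponent,
                n_perm=config.n_perm_gsea,
                seed=net_seed,
                alpha=config.alpha,
                reference_label=ref.study_label,
                query_label=qry.study_label,
            )
            prof.to_tsv(stage_dir / f"profile_{ref.study_label}_vs_{qry.study_label}.tsv")
            profiles.append(prof)
        if region_genes:
            for qry in (top_a, top_b):
                prof = network_enrichment.region_comparison(
                    network, region_genes, qry,
                    sizes=config.sizes,
                    weight_exponent=config.weight_exponent,
                    n_perm=config.n_perm_gsea,
                    seed=net_seed,
                    alpha=config.alpha,
                    query_label=qry.study_label,
                )
                prof.to_tsv(stage_dir / f"profile_region_vs_{qry.study_label}.tsv")
                profiles.append(prof)
        network_enrichment.export_profile_heatmap(
            profiles, stage_dir / "profiles_heatmap.png", alpha=config.alpha
        )
        if config.region is not None:
            frac = network_enrichment.region_snp_fraction(
                result, pairs,
                (config.region.chrom, config.region.start, config.region.end),
            )
            (stage_dir / "region_snp_fraction.json").write_text(
                json.dumps({"percent": frac})
            )
        manifest.wall_clock[stage] = time.perf_counter() - t0
        manifest.stages.append(stage)

        # -------------------------------------------------------- pathways
        stage = "pathways"
        t0 = time.perf_counter()
        stage_dir = out / "pathways"
        stage_dir.mkdir(exist_ok=True)
        # gene sets per cohort: each study's top genes restricted to the universe
        cohort_results = {}
        for label, top in tops.items():
            genes_in = set(top.gene_ids) & set(db.universe)
            if not genes_in:
                logger.warning("%s: no top gene in the pathway universe", label)
                continue
            res = pathway_map.enrich(genes_in, db, alpha_adj=config.alpha_adj)
            res.to_csv(stage_dir / f"{label}_enrichment.tsv", sep="\t", index=False)
            pruned, prune_log = pathway_map.stepdown_prune(
                res[res["significant"]], db, jaccard_max=config.prune_max
            )
            pruned.to_csv(stage_dir / f"{label}_enrichment_pruned.tsv", sep="\t", index=False)
            cohort_results[label] = pruned
            with open(stage_dir / f"{label}_prune_log.tsv", "w") as fh:
                fh.write("discarded\tretained_representative\n")
                for d, r in prune_log:
                    fh.write(f"{d}\t{r}\n")
        if any(len(df) for df in cohort_results.values()):
            graph = pathway_map.build_map(cohort_results, db, edge_min=config.edge_min)
            pathway_map.export_map(graph, stage_dir)
        else:
            logger.warning("no significant pathways; enrichment map skipped")
        named = {label: list(top.gene_ids) for label, top in tops.items()}
        if region_genes:
            named["region"] = region_genes
        try:
            mat = pathway_map.overlap_pathway_comparison(
                named, db, alpha_adj=config.alpha_adj
            )
            mat.to_csv(stage_dir / "pathway_jaccard_matrix.tsv", sep="\t")
        except InputError as exc:
            logger.warning("pathway comparison skipped: %s", exc)
        manifest.wall_clock[stage] = time.perf_counter() - t0
        manifest.stages.append(stage)
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    finally:
        logging.getLogger("ranklap").removeHandler(collector)

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest.checksums[str(f.relative_to(out))] = _sha256(f)
    manifest.to_json(out / "manifest.json")
    return manifest
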