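"""End-to-end orchestration: binarize -> filter -> cluster -> consensus ->
mutual-exclusivity test -> SL calling, with a machine-readable run report.

Every stage is deterministic given the configuration and its seeds, so a
rerun with the same config produces byte-identical output tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import io
from .cna import AlterationMatrix, BinarizeMode, binarize_gistic, filter_genes
from .clustering import (ConsensusMatrix, GeneCluster, build_consensus_matrix,
                         cluster_genes)
from .io import GarpTable, GeneLocusTable, GisticTable, PathwayAnnotation
from .mutex import MEPairResult, call_me_pairs
from .sl import SLCall, SLCallingSummary, call_sl_pairs


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineParams:
    """All tunables of the pipeline, schema-validated before any computation."""

    binarize_mode: str = "homdel"
    min_patients: int | None = None
    min_fraction: float | None = None
    # clustering
    damping: float = 0.9
    max_iter: int = 1000
    convergence_iter: int = 15
    preference: float | None = None
    affinity: str = "neg"
    cluster_seed: int = 0
    # mutual-exclusivity null
    n_graphs: int = 1000
    n_swaps: int | None = None
    null_seed: int = 0
    alpha: float = 0.05
    add_one: bool = False
    seed_genes: list[str] | None = None
    # SL calling
    sl_alpha: float = 0.05
    bh: bool = False
    variants: tuple[str, ...] = ("DD", "ALT")
    min_context: int = 1

    def __post_init__(self) -> None:
        if self.min_patients is not None and self.min_fraction is not None:
            raise ValueError("set exactly one of min_patients / min_fraction")
        BinarizeMode(self.binarize_mode)  # raises on unknown mode
        if not 0 < self.alpha <= 1 or not 0 < self.sl_alpha <= 1:
            raise ValueError("alpha thresholds must be in (0, 1]")
        if self.affinity not in ("neg", "inv"):
            raise ValueError("affinity must be 'neg' or 'inv'")


@dataclass
class PipelineResult:
    matrix: AlterationMatrix
    clusters: list[GeneCluster]
    consensus: ConsensusMatrix
    significant: list[MEPairResult]
    all_pairs: list[MEPairResult]
    hdmi_thresholds: dict[str, float]
    sl_calls: list[SLCall]
    sl_summary: SLCallingSummary | None
    report: dict

    def cluster_of(self, gene: str) -> str:
        for c in self.clusters:
            if gene in c.members:
                return c.exemplar
        raise KeyError(f"gene {gene!r} not in any cluster")


def analyze(gistic: GisticTable, loci: GeneLocusTable,
            garp: GarpTable | None = None,
            ann: PathwayAnnotation | None = None,
            params: PipelineParams | None = None) -> PipelineResult:
    """Run the full analysis in memory and return every intermediate stage."""
    params = params or PipelineParams()
    report: dict = {"n_genes_input": len(gistic.gene_ids),
                    "n_patients": len(gistic.patient_ids)}

    try:
        m = binarize_gistic(gistic, BinarizeMode(params.binarize_mode))
        m = filter_genes(m, params.min_patients, params.min_fraction)
    except (ValueError, KeyError) as e:
        raise PipelineError("binarize/filter", str(e)) from e
    report["n_genes_filtered"] = len(m.gene_ids)

    try:
        clusters = cluster_genes(
            m, loci, damping=params.damping, max_iter=params.max_iter,
            convergence_iter=params.convergence_iter,
            preference=params.preference, affinity=params.affinity,
            seed=params.cluster_seed)
        consensus = build_consensus_matrix(clusters, m)
    except Exception as e:
        raise PipelineError("clustering", str(e)) from e
    report["n_clusters"] = len(clusters)

    seed_clusters = None
    if params.seed_genes:
        gene_to_cluster = {g: c.exemplar for c in clusters for g in c.members}
        missing = [g for g in params.seed_genes if g not in gene_to_cluster]
        if missing:
            raise PipelineError("me_test", f"seed genes not in any cluster: {missing}")
        seed_clusters = sorted({gene_to_cluster[g] for g in params.seed_genes})

    try:
        significant, all_results, thresholds = call_me_pairs(
            consensus, params.alpha, n_graphs=params.n_graphs,
            n_swaps=params.n_swaps, seed=params.null_seed,
            seed_clusters=seed_clusters, add_one=params.add_one)
    except Exception as e:
        raise PipelineError("me_test", str(e)) from e
    report["n_pairs_tested"] = len(all_results)
    report["n_degenerate_pairs"] = sum(r.degenerate for r in all_results)
    report["n_significant_pairs"] = len(significant)

    sl_calls: list[SLCall] = []
    summary = None
    if garp is not None or ann is not None:
        try:
            sl_calls, summary = call_sl_pairs(
                significant, consensus.clusters, garp, ann,
                alpha=params.sl_alpha, bh=params.bh,
                variants=params.variants, min_context=params.min_context)
        except Exception as e:
            raise PipelineError("sl_calling", str(e)) from e
        report["n_sl_calls"] = len(sl_calls)
        report["n_untestable_gene_pairs"] = summary.n_untestable
        report["n_validated_cluster_pairs"] = len(summary.validated_pairs)
        report["n_collateral_gene_pairs"] = sum(
            1 for labs in summary.labels.values()
            for lab in labs.values() if lab == "collateral")
    return PipelineResult(m, clusters, consensus, significant, all_results,
                          thresholds, sl_calls, summary, report)


@dataclass
class PipelineConfig:
    """File-level configuration: input paths plus :class:`PipelineParams`."""

    cna_path: str
    loci_path: str
    gmt_path: str | None = None
    garp_score_path: str | None = None
    garp_status_path: str | None = None
    duplicate_policy: str = "error"
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        params = data.pop("params", {})
        if "variants" in params:
            params["variants"] = tuple(params["variants"])
        return cls(params=PipelineParams(**params), **data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["params"]["variants"] = list(self.params.variants)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Load inputs, run :func:`analyze`, and write results plus a run report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        gistic = io.read_gistic_matrix(cfg.cna_path, cfg.duplicate_policy)
        loci = io.read_gene_loci(cfg.loci_path)
        ann = io.read_gmt(cfg.gmt_path) if cfg.gmt_path else None
        garp = (io.read_garp(cfg.garp_score_path, cfg.garp_status_path)
                if cfg.garp_score_path and cfg.garp_status_path else None)
    except Exception as e:
        raise PipelineError("load", str(e)) from e

    if ann is not None:
        # over-representation universe restricted to analysed genes
        try:
            m = filter_genes(binarize_gistic(gistic, BinarizeMode(cfg.params.binarize_mode)),
                             cfg.params.min_patients, cfg.params.min_fraction)
            ann = ann.restrict_to_universe(m.gene_ids)
        except (ValueError, KeyError) as e:
            raise PipelineError("binarize/filter", str(e)) from e
    result = analyze(gistic, loci, garp, ann, cfg.params)

    io.write_results(result.all_pairs, result.sl_calls, out,
                     clusters=result.consensus.clusters)
    (out / "report.json").write_text(json.dumps(result.report, indent=1, sort_keys=True))
    cfg.to_yaml(out / "config.yaml")
    return result
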