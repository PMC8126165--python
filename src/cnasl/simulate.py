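"""Synthetic CNA cohorts with planted mutually exclusive driver pairs.

The generator mirrors the mechanism that motivates the whole pipeline:
deletions are *segment-level* events, so neighbouring genes inherit nearly
identical profiles structurally rather than by imposed correlation, and
per-patient propensity multipliers make alteration rates heterogeneous
across patients (the reason the naive hypergeometric null fails).  On top of
that background, designated driver segment pairs are sampled jointly with
co-alteration probability eps x (product of marginals): eps = 1 recovers
independence, eps = 0 perfect mutual exclusivity.  Matching GARP screens
(with a planted essentiality shift Delta for the driver gene pair) and GMT
pathway annotations (with a planted overlap k of K_x/K_y draws from N
pathways) make every downstream stage testable offline.

All randomness flows from one master seed through ``numpy`` SeedSequence
spawning: stream 0 drives the patient cohort, stream 1 the GARP screen,
stream 2 the pathway annotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GarpTable, GeneLocusTable, GisticTable, PathwayAnnotation


@dataclass
class DriverPairSpec:
    """A planted mutually exclusive segment pair.

    ``(chrom_a, seg_a)`` and ``(chrom_b, seg_b)`` index the two segments;
    the middle gene of each segment is the named driver.  ``epsilon``
    scales the joint deletion probability relative to independence.
    """

    chrom_a: int = 0
    seg_a: int = 0
    chrom_b: int = 1
    seg_b: int = 0
    epsilon: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort."""

    n_patients: int = 500
    n_chromosomes: int = 4
    segments_per_chromosome: int = 5
    genes_per_segment: int = 5
    gene_spacing_bp: int = 100_000
    segment_spacing_bp: int = 30_000_000
    chromosome_offset_bp: int = 5_000_000
    segment_del_rate: float = 0.10
    segment_rate_jitter: float = 0.25
    within_segment_codeletion: float = 0.95
    background_del_rate: float = 0.005
    propensity_values: tuple[float, ...] = (0.6, 1.9333333333333333)
    propensity_weights: tuple[float, ...] = (0.7, 0.3)
    driver_pairs: list[DriverPairSpec] = field(default_factory=lambda: [DriverPairSpec()])
    # GARP screen
    n_cell_lines: int = 50
    garp_baseline: float = -1.0
    garp_noise_sd: float = 1.0
    garp_delta: float = 3.0
    somatic_mut_rate: float = 0.05
    # pathway annotation
    n_pathways: int = 10
    planted_k: int = 4
    planted_k_x: int = 5
    planted_k_y: int = 4
    background_extra_pathway_prob: float = 0.3
    # GISTIC noise on non-deleted entries
    hemizygous_rate: float = 0.05
    gain_rate: float = 0.05
    amp_rate: float = 0.01
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("segment_del_rate", "within_segment_codeletion",
                     "background_del_rate", "somatic_mut_rate",
                     "background_extra_pathway_prob", "hemizygous_rate",
                     "gain_rate", "amp_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.genes_per_segment < 1:
            raise ValueError("segments need at least one gene")
        if abs(sum(w * v for w, v in zip(self.propensity_weights,
                                         self.propensity_values)) - 1.0) > 1e-6:
            raise ValueError("propensity mixture must have mean 1")
        if not (self.planted_k <= min(self.planted_k_x, self.planted_k_y)
                <= max(self.planted_k_x, self.planted_k_y) <= self.n_pathways):
            raise ValueError("infeasible planted pathway counts")
        need = (self.planted_k + (self.planted_k_x - self.planted_k)
                + (self.planted_k_y - self.planted_k))
        if need > self.n_pathways:
            raise ValueError("planted pathway layout does not fit the universe")

    @property
    def n_segments(self) -> int:
        return self.n_chromosomes * self.segments_per_chromosome

    @property
    def n_genes(self) -> int:
        return self.n_segments * self.genes_per_segment

    def segment_index(self, chrom: int, seg: int) -> int:
        return chrom * self.segments_per_chromosome + seg

    def gene_symbol(self, chrom: int, seg: int, i: int) -> str:
        return f"G{chrom + 1}S{seg + 1}N{i + 1}"

    def driver_gene(self, chrom: int, seg: int) -> str:
        return self.gene_symbol(chrom, seg, self.genes_per_segment // 2)


@dataclass
class SimTruth:
    """Planted structure: per-gene segment labels, driver and collateral pairs."""

    segment_labels: dict[str, int]
    driver_pairs: list[tuple[str, str]]
    collateral_pairs: list[tuple[str, str]]
    driver_segments: list[tuple[int, int]]

    def to_json(self, path: str | Path) -> None:
        data = {
            "segment_labels": self.segment_labels,
            "driver_pairs": [list(p) for p in self.driver_pairs],
            "collateral_pairs": [list(p) for p in self.collateral_pairs],
            "driver_segments": [list(p) for p in self.driver_segments],
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        data = json.loads(Path(path).read_text())
        return cls(
            {g: int(v) for g, v in data["segment_labels"].items()},
            [tuple(p) for p in data["driver_pairs"]],
            [tuple(p) for p in data["collateral_pairs"]],
            [tuple(p) for p in data["driver_segments"]],
        )


def _streams(cfg: SimConfig):
    children = np.random.SeedSequence(cfg.seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def _segment_rates(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    jitter = rng.uniform(1 - cfg.segment_rate_jitter, 1 + cfg.segment_rate_jitter,
                         size=cfg.n_segments)
    return np.clip(cfg.segment_del_rate * jitter, 0.0, 1.0)


def _segment_events(cfg: SimConfig, rng: np.random.Generator,
                    n_samples: int) -> np.ndarray:
    """Sample the segment x sample event matrix, honouring planted pairs."""
    rates = _segment_rates(cfg, rng)
    propensity = rng.choice(cfg.propensity_values, size=n_samples,
                            p=cfg.propensity_weights)
    p_event = np.clip(rates[:, None] * propensity[None, :], 0.0, 1.0)

    events = rng.random((cfg.n_segments, n_samples)) < p_event

    for spec in cfg.driver_pairs:
        sa = cfg.segment_index(spec.chrom_a, spec.seg_a)
        sb = cfg.segment_index(spec.chrom_b, spec.seg_b)
        pa = p_event[sa]
        pb = p_event[sb]
        p11 = spec.epsilon * pa * pb
        p10 = pa - p11
        p01 = pb - p11
        if (p10 + p01 + p11 > 1.0 + 1e-12).any():
            raise ValueError(
                "infeasible driver-pair configuration: marginal deletion "
                "probabilities too large for the requested epsilon"
            )
        u = rng.random(n_samples)
        events[sa] = u < p11 + p10
        events[sb] = (u < p11) | ((u >= p11 + p10) & (u < p11 + p10 + p01))
    return events


def _deletions(cfg: SimConfig, rng: np.random.Generator,
               events: np.ndarray) -> np.ndarray:
    """Gene-level deletion calls given segment events."""
    n_samples = events.shape[1]
    gene_events = np.repeat(events, cfg.genes_per_segment, axis=0)
    u = rng.random((cfg.n_genes, n_samples))
    p = np.where(gene_events, cfg.within_segment_codeletion, cfg.background_del_rate)
    return u < p


def _gene_symbols(cfg: SimConfig) -> list[str]:
    return [cfg.gene_symbol(c, s, i)
            for c in range(cfg.n_chromosomes)
            for s in range(cfg.segments_per_chromosome)
            for i in range(cfg.genes_per_segment)]


def simulate_cohort(cfg: SimConfig) -> tuple[GisticTable, GeneLocusTable, SimTruth]:
    """Generate the GISTIC matrix, loci and planted truth for one cohort."""
    rng, _, _ = _streams(cfg)
    events = _segment_events(cfg, rng, cfg.n_patients)
    deleted = _deletions(cfg, rng, events)

    scores = np.zeros(deleted.shape, dtype=np.int8)
    scores[deleted] = -2
    noise = rng.random(deleted.shape)
    p_hemi = cfg.hemizygous_rate
    p_gain = cfg.gain_rate
    p_amp = cfg.amp_rate
    scores[~deleted & (noise < p_hemi)] = -1
    scores[~deleted & (noise >= p_hemi) & (noise < p_hemi + p_gain)] = 1
    scores[~deleted & (noise >= p_hemi + p_gain) & (noise < p_hemi + p_gain + p_amp)] = 2

    symbols = _gene_symbols(cfg)
    patients = [f"P{i + 1:04d}" for i in range(cfg.n_patients)]
    gistic = GisticTable(symbols, patients, scores)

    rows = []
    for c in range(cfg.n_chromosomes):
        for s in range(cfg.segments_per_chromosome):
            start = cfg.chromosome_offset_bp + s * cfg.segment_spacing_bp
            for i in range(cfg.genes_per_segment):
                rows.append((cfg.gene_symbol(c, s, i), f"chr{c + 1}",
                             start + i * cfg.gene_spacing_bp))
    loci = GeneLocusTable(
        pd.DataFrame(rows, columns=["symbol", "chromosome", "tss_bp"]).set_index("symbol")
    )

    labels = {}
    for c in range(cfg.n_chromosomes):
        for s in range(cfg.segments_per_chromosome):
            for i in range(cfg.genes_per_segment):
                labels[cfg.gene_symbol(c, s, i)] = cfg.segment_index(c, s)
    driver_pairs = []
    collateral = []
    driver_segments = []
    for spec in cfg.driver_pairs:
        x = cfg.driver_gene(spec.chrom_a, spec.seg_a)
        y = cfg.driver_gene(spec.chrom_b, spec.seg_b)
        driver_pairs.append((x, y))
        driver_segments.append((cfg.segment_index(spec.chrom_a, spec.seg_a),
                                cfg.segment_index(spec.chrom_b, spec.seg_b)))
        xs = [cfg.gene_symbol(spec.chrom_a, spec.seg_a, i)
              for i in range(cfg.genes_per_segment)]
        ys = [cfg.gene_symbol(spec.chrom_b, spec.seg_b, i)
              for i in range(cfg.genes_per_segment)]
        collateral.extend((gx, gy) for gx in xs for gy in ys if (gx, gy) != (x, y))
    return gistic, loci, SimTruth(labels, driver_pairs, collateral, driver_segments)


def simulate_garp(truth: SimTruth, cfg: SimConfig) -> GarpTable:
    """Generate a matching GARP screen with the planted essentiality shift.

    Cell lines are fresh samples from the same cohort model; the status table
    marks deleted genes HOMDEL and sprinkles somatic mutations on the rest.
    For each planted driver pair (x, y), the score of x drops by Delta in
    lines where y is altered, and symmetrically for y.
    """
    _, rng, _ = _streams(cfg)
    events = _segment_events(cfg, rng, cfg.n_cell_lines)
    deleted = _deletions(cfg, rng, events)
    somatic = ~deleted & (rng.random(deleted.shape) < cfg.somatic_mut_rate)

    symbols = _gene_symbols(cfg)
    lines = [f"CL{i + 1:03d}" for i in range(cfg.n_cell_lines)]
    status_codes = np.where(deleted, "HOMDEL", np.where(somatic, "SOMATIC_MUT", "WT"))

    scores = cfg.garp_baseline + cfg.garp_noise_sd * rng.standard_normal(deleted.shape)
    altered = deleted | somatic
    index = {g: i for i, g in enumerate(symbols)}
    for x, y in truth.driver_pairs:
        ix, iy = index[x], index[y]
        scores[ix, altered[iy]] -= cfg.garp_delta
        scores[iy, altered[ix]] -= cfg.garp_delta

    score_df = pd.DataFrame(scores, index=symbols, columns=lines)
    status_df = pd.DataFrame(status_codes.T, index=lines, columns=symbols)
    return GarpTable(score_df, status_df)


def simulate_pathways(truth: SimTruth, cfg: SimConfig) -> PathwayAnnotation:
    """Generate a GMT-style annotation with the planted driver overlap.

    Each planted driver pair shares exactly ``planted_k`` of the
    ``n_pathways`` universe with per-gene totals K_x / K_y; background genes
    get 1-2 uniform pathways (sparse-annotation regime).
    """
    _, _, rng = _streams(cfg)
    pathway_ids = [f"PW{i + 1:02d}" for i in range(cfg.n_pathways)]
    membership: dict[str, set[str]] = {p: set() for p in pathway_ids}

    driver_genes = set()
    for x, y in truth.driver_pairs:
        driver_genes.update((x, y))
        order = list(rng.permutation(pathway_ids))
        shared = order[:cfg.planted_k]
        x_extra = order[cfg.planted_k:cfg.planted_k_x]
        y_extra = order[cfg.planted_k_x:
                        cfg.planted_k_x + (cfg.planted_k_y - cfg.planted_k)]
        for p in shared + x_extra:
            membership[p].add(x)
        for p in shared + y_extra:
            membership[p].add(y)

    background = [g for g in truth.segment_labels if g not in driver_genes]
    for g in background:
        size = 1 + int(rng.random() < cfg.background_extra_pathway_prob)
        for p in rng.choice(pathway_ids, size=size, replace=False):
            membership[str(p)].add(g)

    # keep the universe size fixed: an empty pathway gets one background gene
    for p in pathway_ids:
        if not membership[p]:
            membership[p].add(str(rng.choice(background)))

    return PathwayAnnotation({p: frozenset(m) for p, m in membership.items()})


def config_from_dict(data: dict) -> SimConfig:
    data = dict(data)
    if "driver_pairs" in data:
        data["driver_pairs"] = [DriverPairSpec(**d) for d in data["driver_pairs"]]
    if "propensity_values" in data:
        data["propensity_values"] = tuple(data["propensity_values"])
    if "propensity_weights" in data:
        data["propensity_weights"] = tuple(data["propensity_weights"])
    return SimConfig(**data)


def config_to_dict(cfg: SimConfig) -> dict:
    data = asdict(cfg)
    data["propensity_values"] = list(cfg.propensity_values)
    data["propensity_weights"] = list(cfg.propensity_weights)
    return data
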