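"""Grouping of proximal, co-deleted genes into clusters with consensus profiles.

Copy-number events span large genomic segments, so neighbouring genes carry
nearly identical alteration profiles and would flood any per-gene
mutual-exclusivity scan with redundant hits.  Genes are therefore grouped by
a distance that mixes genomic separation with profile co-occurrence,

    D(g1, g2) = dist(g1, g2) / 20 Mb  +  Pr(g1) Pr(g2) / Pr(g1, g2)

on the same chromosome and +inf otherwise, where dist() is the gap between
transcription start sites, Pr(g) = M_g / |P| and Pr(g1, g2) = M_g1g2 / |P|
are empirical alteration probabilities, and the 20 Mb scale corresponds to
roughly 20 cM.  Strong profile overlap (co-occurrence above independence)
shrinks the second term; zero co-occurrence means there is no evidence the
genes are co-deleted and the distance is +inf.

Clustering is exemplar-based message passing (affinity propagation), which
estimates the number of clusters itself; it runs per chromosome, which is
exact under the infinite inter-chromosome distance and guarantees chromosome
purity.  Each cluster is summarised by a majority-vote *consensus gene*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from .cna import AlterationMatrix
from .io import GeneLocusTable

TWENTY_MEGABASES = 20_000_000.0


class ClusteringError(RuntimeError):
    pass


@dataclass
class GeneCluster:
    members: list[str]
    exemplar: str
    chromosome: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty cluster")
        if self.exemplar not in self.members:
            raise ValueError("exemplar must be a cluster member")


@dataclass
class ConsensusMatrix:
    """Binary cluster x patient matrix of consensus-gene profiles."""

    cluster_ids: list[str]
    patient_ids: list[str]
    C: np.ndarray
    clusters: dict[str, GeneCluster] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=np.uint8)
        if self.C.shape != (len(self.cluster_ids), len(self.patient_ids)):
            raise ValueError("consensus matrix shape mismatch")
        if not np.isin(self.C, [0, 1]).all():
            raise ValueError("consensus matrix must be binary")
        self._index = {c: i for i, c in enumerate(self.cluster_ids)}

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def row(self, cluster_id: str) -> np.ndarray:
        return self.C[self._index[cluster_id]]


def gene_distance(g1: str, g2: str, loci: GeneLocusTable, m: AlterationMatrix) -> float:
    """Pairwise gene distance D; +inf across chromosomes or at zero co-occurrence."""
    for g in (g1, g2):
        if g not in loci:
            raise KeyError(f"gene {g!r} missing from locus table")
    r1, r2 = m.row(g1), m.row(g2)  # raises on unknown gene
    if loci.chromosome(g1) != loci.chromosome(g2):
        return float("inf")
    n = m.n_patients
    p1 = r1.sum() / n
    p2 = r2.sum() / n
    p12 = int((r1 & r2).sum()) / n
    if p12 == 0.0:
        return float("inf")
    return abs(loci.tss(g1) - loci.tss(g2)) / TWENTY_MEGABASES + (p1 * p2) / p12


def _distance_matrix(sub: np.ndarray, tss: np.ndarray, n_patients: int) -> np.ndarray:
    p = sub.sum(axis=1) / n_patients
    joint = (sub.astype(np.float64) @ sub.T.astype(np.float64)) / n_patients
    genomic = np.abs(tss[:, None] - tss[None, :]) / TWENTY_MEGABASES
    with np.errstate(divide="ignore", invalid="ignore"):
        D = genomic + (p[:, None] * p[None, :]) / joint
    D[joint == 0] = np.inf
    np.fill_diagonal(D, 0.0)
    return D


def _similarity(D: np.ndarray, affinity: str) -> np.ndarray:
    finite = np.isfinite(D) & ~np.eye(len(D), dtype=bool)
    if affinity == "neg":
        S = -D
    elif affinity == "inv":
        with np.errstate(divide="ignore"):
            S = 1.0 / D
        # zero distances (identical TSS + perfect overlap) map to the top of
        # the finite similarity range rather than +inf
        pos_inf = np.isinf(S) & (S > 0)
        if pos_inf.any():
            cap = np.max(S[finite & np.isfinite(S)], initial=1.0) * 10
            S[pos_inf] = cap
    else:
        raise ValueError(f"unknown affinity {affinity!r} (use 'neg' or 'inv')")
    fin = S[np.isfinite(S) & finite]
    if fin.size:
        span = float(fin.max() - fin.min())
        floor = float(fin.min()) - (span + 1.0)
    else:
        floor = -1.0
    S[~np.isfinite(S)] = floor
    np.fill_diagonal(S, 0.0)  # overwritten by the preference below
    return S


def cluster_genes(m: AlterationMatrix, loci: GeneLocusTable, *,
                  damping: float = 0.9, max_iter: int = 1000,
                  convergence_iter: int = 15, preference: float | None = None,
                  affinity: str = "neg", seed: int = 0) -> list[GeneCluster]:
    """Partition all genes into chromosome-pure clusters via affinity propagation.

    ``preference`` defaults to the median of the off-diagonal similarities on
    each chromosome (the common self-responsibility default, which lets the
    algorithm pick the number of exemplars).  ``affinity`` selects how the
    distance D becomes a similarity: ``"neg"`` (-D, the standard message-
    passing convention, default) or ``"inv"`` (1/D).
    """
    missing = [g for g in m.gene_ids if g not in loci]
    if missing:
        raise KeyError(f"genes missing from locus table: {missing[:5]}")
    by_chrom: dict[str, list[int]] = {}
    for i, g in enumerate(m.gene_ids):
        by_chrom.setdefault(loci.chromosome(g), []).append(i)

    clusters: list[GeneCluster] = []
    for chrom in sorted(by_chrom):
        idx = by_chrom[chrom]
        genes = [m.gene_ids[i] for i in idx]
        if len(idx) == 1:
            clusters.append(GeneCluster(genes, genes[0], chrom))
            continue
        sub = m.M[idx]
        tss = np.array([loci.tss(g) for g in genes], dtype=np.float64)
        D = _distance_matrix(sub, tss, m.n_patients)
        S = _similarity(D, affinity)
        off = S[~np.eye(len(S), dtype=bool)]
        pref = float(np.median(off)) if preference is None else preference
        ap = AffinityPropagation(
            affinity="precomputed", damping=damping, max_iter=max_iter,
            convergence_iter=convergence_iter, preference=pref,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                labels = ap.fit_predict(S)
            except ConvergenceWarning:
                raise ClusteringError(
                    f"affinity propagation did not converge on {chrom} within "
                    f"{max_iter} iterations; try raising damping or lowering "
                    "the preference"
                ) from None
        if len(ap.cluster_centers_indices_) == 0 or (labels < 0).any():
            raise ClusteringError(
                f"affinity propagation found no exemplars on {chrom}; "
                "adjust damping/preference"
            )
        for lab in np.unique(labels):
            member_idx = np.flatnonzero(labels == lab)
            exemplar = genes[int(ap.cluster_centers_indices_[lab])]
            clusters.append(GeneCluster([genes[int(i)] for i in member_idx],
                                        exemplar, chrom))
    return clusters


def consensus_profile(c: GeneCluster, m: AlterationMatrix) -> np.ndarray:
    """Majority-vote binary profile: 1 iff strictly more than half the members
    are altered in a patient (a tie in an even-size cluster is not a majority).
    """
    rows = np.stack([m.row(g) for g in c.members])
    counts = rows.sum(axis=0)
    return (2 * counts > len(c.members)).astype(np.uint8)


def build_consensus_matrix(clusters: list[GeneCluster], m: AlterationMatrix) -> ConsensusMatrix:
    """Stack consensus profiles into a cluster x patient matrix.

    The clusters must partition the gene set of ``m`` exactly; cluster IDs
    are the exemplar symbols.
    """
    seen: dict[str, str] = {}
    for c in clusters:
        for g in c.members:
            if g in seen:
                raise ValueError(f"gene {g!r} assigned to two clusters")
            seen[g] = c.exemplar
    missing = [g for g in m.gene_ids if g not in seen]
    if missing:
        raise ValueError(f"genes not covered by any cluster: {missing[:5]}")
    profiles = np.stack([consensus_profile(c, m) for c in clusters])
    ids = [c.exemplar for c in clusters]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate exemplar symbols across clusters")
    return ConsensusMatrix(ids, list(m.patient_ids), profiles,
                           {c.exemplar: c for c in clusters})
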