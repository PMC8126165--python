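"""Mutual-exclusivity scoring of consensus-gene pairs.

The score is HDMI ("Hamming distance minus intersection"),

    HDMI(a, b) = (M_a + M_b - 3 M_ab) / |P|,

the number of patients altered in exactly one of the two consensus genes
minus the number altered in both, normalised by cohort size.  HDMI has no
universal significance threshold (it deliberately favours frequently altered
genes), so significance is empirical: the consensus x patient matrix is read
as a bipartite graph, an ensemble of degree-preserving random graphs is
generated by legal two-edge swaps, and the p-value of a pair is the fraction
of null graphs whose co-alteration count M^i_ab is <= the observed M_ab.
Conditioning on both patient and gene degrees is what separates this null
from the naive hypergeometric test, which wrongly assumes homogeneous
per-patient and per-gene alteration rates.

The null ensemble depends only on the matrix margins, so it is generated
once per consensus matrix and shared across all pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from ._swaps import swap_edges
from .clustering import ConsensusMatrix

_SEED_MOD = 2**31


@dataclass
class BipartiteAlterationGraph:
    """Patient / consensus-gene bipartite graph as a boolean incidence matrix.

    An edge (p, c) exists iff consensus gene c is altered in patient p; the
    matrix representation makes duplicate edges impossible by construction.
    """

    cluster_ids: list[str]
    patient_ids: list[str]
    adj: np.ndarray  # bool, clusters x patients

    def __post_init__(self) -> None:
        self.adj = np.asarray(self.adj, dtype=bool)
        if self.adj.shape != (len(self.cluster_ids), len(self.patient_ids)):
            raise ValueError("incidence matrix shape mismatch")

    @property
    def n_edges(self) -> int:
        return int(self.adj.sum())

    @property
    def cluster_degrees(self) -> np.ndarray:
        return self.adj.sum(axis=1).astype(np.int64)

    @property
    def patient_degrees(self) -> np.ndarray:
        return self.adj.sum(axis=0).astype(np.int64)

    def edges(self) -> list[tuple[str, str]]:
        ci, pi = np.nonzero(self.adj)
        return [(self.patient_ids[p], self.cluster_ids[c]) for c, p in zip(ci, pi)]


@dataclass
class MEPairResult:
    cluster_a: str
    cluster_b: str
    m_a: int
    m_b: int
    m_ab: int
    hdmi: float
    p_value: float
    n_null: int
    degenerate: bool = False


def hdmi(m_a: int, m_b: int, m_ab: int, n_patients: int) -> float:
    """HDMI(a,b) = (M_a + M_b - 3 M_ab)/|P|; negative under strong overlap."""
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    if min(m_a, m_b, m_ab) < 0:
        raise ValueError("counts must be non-negative")
    if m_ab > min(m_a, m_b):
        raise ValueError("M_ab cannot exceed min(M_a, M_b)")
    if max(m_a, m_b) > n_patients:
        raise ValueError("per-gene counts cannot exceed the cohort size")
    return (m_a + m_b - 3 * m_ab) / n_patients


def build_bipartite(cm: ConsensusMatrix) -> BipartiteAlterationGraph:
    return BipartiteAlterationGraph(list(cm.cluster_ids), list(cm.patient_ids),
                                    cm.C.astype(bool))


def swap_randomize(g: BipartiteAlterationGraph, n_swaps: int,
                   seed: int) -> BipartiteAlterationGraph:
    """Return a degree-preserving randomization of ``g``.

    ``n_swaps`` counts *attempted* swaps; rejected (illegal) proposals consume
    an attempt.  Deterministic for a given seed.
    """
    if n_swaps < 0:
        raise ValueError("n_swaps must be >= 0")
    adj = g.adj.copy()
    if g.n_edges < 2:
        warnings.warn("graph has < 2 edges; returned unchanged")
        return BipartiteAlterationGraph(list(g.cluster_ids), list(g.patient_ids), adj)
    ci, pi = np.nonzero(adj)
    swap_edges(adj, ci.astype(np.int64), pi.astype(np.int64),
               int(n_swaps), int(seed) % _SEED_MOD)
    return BipartiteAlterationGraph(list(g.cluster_ids), list(g.patient_ids), adj)


def _cooccurrence(adj: np.ndarray) -> np.ndarray:
    A = adj.astype(np.float64)
    return np.rint(A @ A.T).astype(np.int64)


class NullEnsemble:
    """Shared degree-preserving null for all pairs of one consensus matrix.

    For each of ``n_graphs`` randomizations (graph i seeded with
    ``seed + i`` for reproducible regeneration) the full pairwise
    co-alteration matrix M^i_ab is computed, and two statistics are
    accumulated per pair: the count of graphs with M^i_ab <= observed M_ab
    (the empirical p-value numerator) and the count with M^i_ab == M_ab
    (used for mid-p diagnostics).
    """

    def __init__(self, cm: ConsensusMatrix, n_graphs: int = 1000,
                 n_swaps: int | None = None, seed: int = 0) -> None:
        if n_graphs < 1:
            raise ValueError("n_graphs must be >= 1")
        self.cm = cm
        self.graph = build_bipartite(cm)
        self.n_graphs = int(n_graphs)
        self.n_swaps = int(10 * self.graph.n_edges if n_swaps is None else n_swaps)
        self.seed = int(seed)
        self.obs = _cooccurrence(self.graph.adj)
        self._counts_le: np.ndarray | None = None
        self._counts_eq: np.ndarray | None = None

    def _run(self) -> None:
        base = self.graph.adj
        le = np.zeros_like(self.obs)
        eq = np.zeros_like(self.obs)
        ci0, pi0 = np.nonzero(base)
        ci0 = ci0.astype(np.int64)
        pi0 = pi0.astype(np.int64)
        for i in range(self.n_graphs):
            adj = base.copy()
            if len(ci0) >= 2:
                swap_edges(adj, ci0.copy(), pi0.copy(), self.n_swaps,
                           (self.seed + i) % _SEED_MOD)
            null = _cooccurrence(adj)
            le += null <= self.obs
            eq += null == self.obs
        self._counts_le = le
        self._counts_eq = eq

    @property
    def counts_le(self) -> np.ndarray:
        if self._counts_le is None:
            self._run()
        return self._counts_le

    @property
    def counts_eq(self) -> np.ndarray:
        if self._counts_eq is None:
            self._run()
        return self._counts_eq

    def result(self, cluster_a: str, cluster_b: str,
               add_one: bool = False) -> MEPairResult:
        ia = self.cm.cluster_ids.index(cluster_a)
        ib = self.cm.cluster_ids.index(cluster_b)
        m_a = int(self.obs[ia, ia])
        m_b = int(self.obs[ib, ib])
        m_ab = int(self.obs[ia, ib])
        score = hdmi(m_a, m_b, m_ab, self.cm.n_patients)
        if m_a == 0 or m_b == 0:
            return MEPairResult(cluster_a, cluster_b, m_a, m_b, m_ab, score,
                                1.0, self.n_graphs, degenerate=True)
        count = int(self.counts_le[ia, ib])
        p = (count + 1) / (self.n_graphs + 1) if add_one else count / self.n_graphs
        return MEPairResult(cluster_a, cluster_b, m_a, m_b, m_ab, score,
                            p, self.n_graphs)

    def all_pairs(self, pairs=None, add_one: bool = False) -> list[MEPairResult]:
        ids = self.cm.cluster_ids
        if pairs is None:
            pairs = [(ids[i], ids[j]) for i in range(len(ids))
                     for j in range(i + 1, len(ids))]
        return [self.result(a, b, add_one=add_one) for a, b in pairs]

    def mid_p(self) -> np.ndarray:
        """Mid-p values for all pairs (upper triangle), for calibration checks."""
        n = len(self.cm.cluster_ids)
        iu = np.triu_indices(n, k=1)
        le = self.counts_le[iu].astype(float)
        eq = self.counts_eq[iu].astype(float)
        return (le - 0.5 * eq) / self.n_graphs


def me_pvalue(cm: ConsensusMatrix, pair: tuple[str, str], n_graphs: int = 1000,
              n_swaps: int | None = None, seed: int = 0) -> MEPairResult:
    """Empirical mutual-exclusivity p-value for a single consensus-gene pair.

    For testing many pairs of the same matrix, build one :class:`NullEnsemble`
    instead; the ensemble depends only on the margins and is shared.
    """
    return NullEnsemble(cm, n_graphs, n_swaps, seed).result(*pair)


def call_me_pairs(cm: ConsensusMatrix, alpha: float = 0.05, *,
                  n_graphs: int = 1000, n_swaps: int | None = None,
                  seed: int = 0, seed_clusters: list[str] | None = None,
                  add_one: bool = False):
    """Evaluate cluster pairs and keep those with p < alpha.

    ``seed_clusters`` restricts testing to pairs involving the given cluster
    IDs (the study seeds, e.g. the clusters of the seven DNA-damage-response
    genes).  Returns ``(significant, all_results, hdmi_thresholds)`` where
    ``hdmi_thresholds[c]`` is the minimum HDMI among the significant partners
    of seed cluster c — the per-seed HDMI value implied by the alpha cut.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    ids = list(cm.cluster_ids)
    if seed_clusters:
        unknown = [c for c in seed_clusters if c not in ids]
        if unknown:
            raise KeyError(f"unknown seed clusters: {unknown}")
        pairs = []
        seen = set()
        for s in seed_clusters:
            for other in ids:
                if other == s:
                    continue
                key = tuple(sorted((s, other)))
                if key not in seen:
                    seen.add(key)
                    pairs.append(key)
    else:
        pairs = None
    ens = NullEnsemble(cm, n_graphs, n_swaps, seed)
    results = ens.all_pairs(pairs, add_one=add_one)
    significant = [r for r in results if not r.degenerate and r.p_value < alpha]
    thresholds: dict[str, float] = {}
    for s in (seed_clusters or ids):
        partners = [r.hdmi for r in significant
                    if s in (r.cluster_a, r.cluster_b)]
        if partners:
            thresholds[s] = min(partners)
    return significant, results, thresholds


def baseline_hypergeom(n_patients: int, m_a: int, m_b: int, m_ab: int) -> float:
    """Naive per-pair test: lower-tail hypergeometric P(X <= M_ab).

    X is the overlap of M_a and M_b patients drawn independently from |P|;
    this is the baseline the degree-conditioned swap null improves upon.
    """
    if not (0 <= m_a <= n_patients and 0 <= m_b <= n_patients):
        raise ValueError("per-gene counts must lie in [0, |P|]")
    if not (max(0, m_a + m_b - n_patients) <= m_ab <= min(m_a, m_b)):
        raise ValueError("M_ab incompatible with the margins")
    return float(hypergeom.cdf(m_ab, n_patients, m_a, m_b))
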