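"""Binary alteration matrix and 2x2 contingency utilities.

Discrete GISTIC scores become a binary gene x patient matrix ``M`` with
``M[i, j] = 1`` when patient *j* carries the chosen alteration of gene *i*
(homozygous deletion by default), followed by the minimum-recurrence gene
filter (>= 50 altered patients in the original cohort, or an equivalent
cohort fraction).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import GisticTable


class BinarizeMode(enum.Enum):
    """Which GISTIC scores count as "altered"."""

    HOMDEL = "homdel"    # score == -2
    ANY_DEL = "any_del"  # score <= -1
    ANY_ALT = "any_alt"  # score != 0


@dataclass
class AlterationMatrix:
    """Binary gene x patient alteration matrix M."""

    gene_ids: list[str]
    patient_ids: list[str]
    M: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.uint8)
        if self.M.shape != (len(self.gene_ids), len(self.patient_ids)):
            raise ValueError("matrix shape does not match axis labels")
        if not np.isin(self.M, [0, 1]).all():
            raise ValueError("alteration matrix must be binary")
        if not self.patient_ids:
            raise ValueError("alteration matrix needs at least one patient")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def gene_counts(self) -> np.ndarray:
        """M_g: number of altered patients per gene (row sums)."""
        return self.M.sum(axis=1).astype(np.int64)

    @property
    def patient_counts(self) -> np.ndarray:
        return self.M.sum(axis=0).astype(np.int64)

    def row(self, gene: str) -> np.ndarray:
        try:
            return self.M[self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"unknown gene {gene!r}") from None


@dataclass
class ContingencyTable2x2:
    """Joint alteration counts for a gene pair (A, B) over the cohort.

    n11 = altered in both, n10 = A only, n01 = B only, n00 = neither.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        for name in ("n11", "n10", "n01", "n00"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


class RateCondition(enum.Enum):
    A_MUT = "a_mut"
    A_WT = "a_wt"


def binarize_gistic(g: GisticTable, mode: BinarizeMode = BinarizeMode.HOMDEL) -> AlterationMatrix:
    """Binarize GISTIC scores; the default keeps homozygous deletions only."""
    if mode is BinarizeMode.HOMDEL:
        M = (g.scores == -2)
    elif mode is BinarizeMode.ANY_DEL:
        M = (g.scores <= -1)
    elif mode is BinarizeMode.ANY_ALT:
        M = (g.scores != 0)
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown binarization mode {mode!r}")
    return AlterationMatrix(list(g.gene_ids), list(g.patient_ids), M.astype(np.uint8))


def filter_genes(m: AlterationMatrix,
                 min_patients: int | None = None,
                 min_fraction: float | None = None) -> AlterationMatrix:
    """Keep genes altered in at least ``min_patients`` patients (inclusive).

    Exactly one of ``min_patients`` / ``min_fraction`` may be given;
    with neither, the cohort-count default of 50 applies.  ``min_fraction``
    translates to ``ceil(min_fraction * n_patients)`` for cohorts whose size
    differs from the original study.
    """
    if min_patients is not None and min_fraction is not None:
        raise ValueError("set exactly one of min_patients / min_fraction")
    if min_patients is None:
        min_patients = (int(np.ceil(min_fraction * m.n_patients))
                        if min_fraction is not None else 50)
    if min_patients < 0:
        raise ValueError("min_patients must be >= 0")
    keep = m.gene_counts >= min_patients
    if not keep.any():
        raise ValueError(
            f"no gene is altered in >= {min_patients} patients; "
            "reduce the recurrence threshold"
        )
    genes = [g for g, k in zip(m.gene_ids, keep) if k]
    return AlterationMatrix(genes, list(m.patient_ids), m.M[keep])


def pair_contingency(m: AlterationMatrix, gene_a: str, gene_b: str) -> ContingencyTable2x2:
    """2x2 cross-classification of patients by alteration state of two genes."""
    a = m.row(gene_a).astype(bool)
    b = m.row(gene_b).astype(bool)
    return ContingencyTable2x2(
        n11=int((a & b).sum()),
        n10=int((a & ~b).sum()),
        n01=int((~a & b).sum()),
        n00=int((~a & ~b).sum()),
    )


def conditional_rate(t: ContingencyTable2x2, condition: RateCondition) -> float:
    """Percentage of B-altered samples within the stratum fixed by A's state.

    ``A_MUT`` -> 100 * n11/(n11+n10); ``A_WT`` -> 100 * n01/(n01+n00).
    A doubling of the rate between the two strata is the signature of
    non-independent alteration ("the probability of a mutation on B depends
    on whether A is mutated"), which is what invalidates the naive
    hypergeometric null for mutual-exclusivity testing.
    """
    if condition is RateCondition.A_MUT:
        denom = t.n11 + t.n10
        if denom == 0:
            raise ValueError("no samples with A altered")
        return 100.0 * t.n11 / denom
    denom = t.n01 + t.n00
    if denom == 0:
        raise ValueError("no samples with A wild type")
    return 100.0 * t.n01 / denom
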