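"""Resolving driver synthetic-lethal gene pairs inside mutually exclusive
cluster pairs.

A significant cluster pair (X, Y) says only that *some* gene pair
(x in X, y in Y) is a plausible synthetic-lethal (SL) driver; the mutual
exclusivity of every other pair is inherited from segment-level co-deletion
(collateral lethality).  Two evidence channels separate the driver from the
passengers:

* **Pathway over-representation** — genes annotated to K_x and K_y of N
  pathways share k of them; an upper-tail hypergeometric test asks whether k
  exceeds the overlap expected for independent annotation.  This is the
  identification test (optionally Benjamini-Hochberg adjusted within the
  cluster pair).
* **GARP essentiality shift** — in shRNA screens, a gene's GARP score (lower
  = more essential) should drop in cell lines where its partner is altered.
  Cell lines are split into (a) both wild type, (b) x WT / y altered,
  (c) x altered / y WT (lines altered in both genes belong to none), and the
  pair passes when median GARP of x on (b) < on (a) and of y on (c) < on
  (a), both strictly.  "Altered" is deep deletion only (variant DD) or deep
  deletion plus somatic mutation (variant ALT).

A gene pair is called SL when the pathway test passes; GARP passes are
recorded as validation evidence (and identify on their own only when the
pair carries no pathway annotation at all).  Remaining pairs in a cluster
pair with a call are labelled collateral; pairs testable by neither channel
are labelled untestable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GarpTable, PathwayAnnotation
from .mutex import MEPairResult

EVIDENCE_GARP_DD = "GARP_DD"
EVIDENCE_GARP_ALT = "GARP_ALT"
EVIDENCE_PATHWAY = "PATHWAY"

ALTERED_BY_VARIANT = {
    "DD": frozenset({"HOMDEL"}),
    "ALT": frozenset({"HOMDEL", "SOMATIC_MUT"}),
}


class NotTestableError(RuntimeError):
    """A gene pair cannot be evaluated by a channel (missing data/contexts)."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class CellLineContexts:
    """Cell-line subsets (a) both WT, (b) y altered, (c) x altered."""

    a: list[str]
    b: list[str]
    c: list[str]
    variant: str

    def __post_init__(self) -> None:
        sets = [set(self.a), set(self.b), set(self.c)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("cell-line contexts must be pairwise disjoint")


@dataclass
class GarpTestResult:
    passed: bool
    variant: str
    med_x_a: float
    med_x_b: float
    med_y_a: float
    med_y_c: float
    n_a: int
    n_b: int
    n_c: int


@dataclass
class PathwayTestResult:
    p: float
    k: int
    k_x: int
    k_y: int
    n_universe: int
    p_adj: float | None = None


@dataclass
class SLCall:
    gene_x: str
    gene_y: str
    cluster_a: str
    cluster_b: str
    evidence: set[str]
    garp: dict[str, GarpTestResult] = field(default_factory=dict)
    pathway: PathwayTestResult | None = None
    collateral_partners: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("a positive SL call needs non-empty evidence")

    def as_row(self) -> dict:
        g = self.garp.get("ALT") or self.garp.get("DD")
        pw = self.pathway
        return {
            "gene_x": self.gene_x, "gene_y": self.gene_y,
            "cluster_a": self.cluster_a, "cluster_b": self.cluster_b,
            "evidence": "|".join(sorted(self.evidence)),
            "garp_variant": g.variant if g else "NA",
            "med_x_wt": f"{g.med_x_a:.4g}" if g else "NA",
            "med_x_partner_alt": f"{g.med_x_b:.4g}" if g else "NA",
            "med_y_wt": f"{g.med_y_a:.4g}" if g else "NA",
            "med_y_partner_alt": f"{g.med_y_c:.4g}" if g else "NA",
            "n_both_wt": g.n_a if g else "NA",
            "n_y_alt": g.n_b if g else "NA",
            "n_x_alt": g.n_c if g else "NA",
            "k_shared": pw.k if pw else "NA",
            "K_x": pw.k_x if pw else "NA",
            "K_y": pw.k_y if pw else "NA",
            "N_pathways": pw.n_universe if pw else "NA",
            "p_pathway_raw": f"{pw.p:.6g}" if pw else "NA",
            "p_pathway_adj": f"{pw.p_adj:.6g}" if pw and pw.p_adj is not None else "NA",
            "collateral_partners": ",".join(f"{x}~{y}" for x, y in self.collateral_partners),
        }


def partition_cell_lines(garp: GarpTable, x: str, y: str,
                         variant: str = "ALT") -> CellLineContexts:
    """Split cell lines into the (a)/(b)/(c) contexts for a gene pair.

    Lines altered in both genes are excluded.  Raises
    :class:`NotTestableError` naming the first empty context.
    """
    if variant not in ALTERED_BY_VARIANT:
        raise ValueError(f"unknown variant {variant!r} (use 'DD' or 'ALT')")
    altered = ALTERED_BY_VARIANT[variant]
    for g in (x, y):
        if g not in garp.status.columns:
            raise NotTestableError(f"gene {g!r} absent from the status table")
    sx = garp.status[x]
    sy = garp.status[y]
    x_alt = sx.isin(altered)
    y_alt = sy.isin(altered)
    a = list(garp.status.index[~x_alt & ~y_alt])
    b = list(garp.status.index[~x_alt & y_alt])
    c = list(garp.status.index[x_alt & ~y_alt])
    for name, lines in (("a", a), ("b", b), ("c", c)):
        if not lines:
            raise NotTestableError(
                f"context ({name}) is empty for pair ({x}, {y}) under {variant}"
            )
    return CellLineContexts(a, b, c, variant)


def _median(garp: GarpTable, gene: str, lines: list[str]) -> float:
    if gene not in garp.scores.index:
        raise NotTestableError(f"no GARP scores for gene {gene!r}")
    vals = garp.scores.loc[gene, lines].to_numpy(dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise NotTestableError(f"all GARP scores missing for {gene!r} in a context")
    return float(np.median(vals))


def garp_sl_test(garp: GarpTable, x: str, y: str,
                 contexts: CellLineContexts) -> GarpTestResult:
    """Strict two-sided essentiality-shift test on context medians."""
    med_x_a = _median(garp, x, contexts.a)
    med_x_b = _median(garp, x, contexts.b)
    med_y_a = _median(garp, y, contexts.a)
    med_y_c = _median(garp, y, contexts.c)
    passed = (med_x_b < med_x_a) and (med_y_c < med_y_a)
    return GarpTestResult(passed, contexts.variant, med_x_a, med_x_b,
                          med_y_a, med_y_c,
                          len(contexts.a), len(contexts.b), len(contexts.c))


def pathway_overlap_test(ann: PathwayAnnotation, x: str, y: str) -> PathwayTestResult:
    """Upper-tail hypergeometric test on the shared-pathway count.

    With K_y pathways drawn without replacement from the N-pathway universe
    and pathways(x) as success states, returns P(overlap >= k).
    """
    px = ann.gene_pathways.get(x)
    py = ann.gene_pathways.get(y)
    if not px:
        raise NotTestableError(f"gene {x!r} has no pathway annotations")
    if not py:
        raise NotTestableError(f"gene {y!r} has no pathway annotations")
    n = ann.universe_size
    k_x, k_y = len(px), len(py)
    if n < max(k_x, k_y):
        raise ValueError("pathway universe smaller than a gene's annotation count")
    k = len(px & py)
    p = float(hypergeom.sf(k - 1, n, k_x, k_y))
    return PathwayTestResult(p, k, k_x, k_y, n)


@dataclass
class SLCallingSummary:
    """Per-cluster-pair label bookkeeping from :func:`call_sl_pairs`."""

    labels: dict[tuple[str, str], dict[tuple[str, str], str]]
    n_untestable: int
    validated_pairs: list[tuple[str, str]]  # cluster pairs with PATHWAY+GARP gene pair


def call_sl_pairs(me_results: list[MEPairResult], clusters: dict,
                  garp: GarpTable | None, ann: PathwayAnnotation | None,
                  alpha: float = 0.05, bh: bool = False,
                  variants: tuple[str, ...] = ("DD", "ALT"),
                  min_context: int = 1) -> tuple[list[SLCall], SLCallingSummary]:
    """Evaluate every gene pair of each significant cluster pair.

    ``clusters`` maps cluster ID -> object with ``members``.  ``bh`` switches
    the identification threshold from raw to Benjamini-Hochberg adjusted
    pathway p-values (adjusted within each cluster pair; both are always
    recorded).  ``min_context`` floors the (a)/(b)/(c) context sizes for the
    GARP channel.
    """
    calls: list[SLCall] = []
    labels: dict[tuple[str, str], dict[tuple[str, str], str]] = {}
    validated: list[tuple[str, str]] = []
    n_untestable = 0

    for me in me_results:
        key = (me.cluster_a, me.cluster_b)
        gene_pairs = [(x, y) for x in clusters[me.cluster_a].members
                      for y in clusters[me.cluster_b].members]

        pw_results: dict[tuple[str, str], PathwayTestResult] = {}
        if ann is not None:
            for pair in gene_pairs:
                try:
                    pw_results[pair] = pathway_overlap_test(ann, *pair)
                except NotTestableError:
                    pass
            if pw_results:
                keys = list(pw_results)
                raw = [pw_results[k].p for k in keys]
                adj = multipletests(raw, method="fdr_bh")[1]
                for k, a_p in zip(keys, adj):
                    pw_results[k].p_adj = float(a_p)

        garp_results: dict[tuple[str, str], dict[str, GarpTestResult]] = {}
        if garp is not None:
            for pair in gene_pairs:
                per_variant: dict[str, GarpTestResult] = {}
                for variant in variants:
                    try:
                        ctx = partition_cell_lines(garp, *pair, variant=variant)
                        if min(len(ctx.a), len(ctx.b), len(ctx.c)) < min_context:
                            raise NotTestableError("context below the size floor")
                        per_variant[variant] = garp_sl_test(garp, *pair, ctx)
                    except NotTestableError:
                        pass
                if per_variant:
                    garp_results[pair] = per_variant

        pair_labels: dict[tuple[str, str], str] = {}
        pair_calls: list[SLCall] = []
        for pair in gene_pairs:
            pw = pw_results.get(pair)
            gr = garp_results.get(pair, {})
            evidence: set[str] = set()
            if gr.get("DD") and gr["DD"].passed:
                evidence.add(EVIDENCE_GARP_DD)
            if gr.get("ALT") and gr["ALT"].passed:
                evidence.add(EVIDENCE_GARP_ALT)
            pw_pass = False
            if pw is not None:
                p_for_call = pw.p_adj if (bh and pw.p_adj is not None) else pw.p
                pw_pass = p_for_call < alpha
            if pw_pass:
                evidence.add(EVIDENCE_PATHWAY)

            identified = pw_pass or (pw is None and bool(evidence))
            if identified:
                call = SLCall(pair[0], pair[1], me.cluster_a, me.cluster_b,
                              evidence, gr, pw)
                pair_calls.append(call)
                pair_labels[pair] = "sl"
                if EVIDENCE_PATHWAY in evidence and (
                        EVIDENCE_GARP_DD in evidence or EVIDENCE_GARP_ALT in evidence):
                    if key not in validated:
                        validated.append(key)
            elif pw is None and not gr:
                pair_labels[pair] = "untestable"
                n_untestable += 1
            else:
                pair_labels[pair] = "collateral"

        collateral = [p for p, lab in pair_labels.items() if lab == "collateral"]
        for call in pair_calls:
            call.collateral_partners = collateral
        calls.extend(pair_calls)
        labels[key] = pair_labels

    return calls, SLCallingSummary(labels, n_untestable, validated)
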