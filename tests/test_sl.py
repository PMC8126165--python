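import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from cnasl.clustering import GeneCluster
from cnasl.io import GarpTable, PathwayAnnotation
from cnasl.mutex import MEPairResult
from cnasl.sl import (EVIDENCE_GARP_ALT, EVIDENCE_GARP_DD, EVIDENCE_PATHWAY,
                      NotTestableError, call_sl_pairs, garp_sl_test,
                      partition_cell_lines, pathway_overlap_test)


def _garp(status_rows: dict[str, list[str]], score_rows: dict[str, list[float]] | None = None):
    """status_rows: gene -> per-line codes; score_rows: gene -> per-line scores."""
    genes = list(status_rows)
    n = len(next(iter(status_rows.values())))
    lines = [f"c{i}" for i in range(n)]
    status = pd.DataFrame({g: status_rows[g] for g in genes}, index=lines)
    if score_rows is None:
        score_rows = {g: [-1.0] * n for g in genes}
    scores = pd.DataFrame({l: [score_rows[g][i] for g in genes]
                           for i, l in enumerate(lines)}, index=genes)
    return GarpTable(scores, status)


class TestPartitionCellLines:
    def test_four_line_example_under_alt(self):
        garp = _garp({"x": ["WT", "WT", "SOMATIC_MUT", "HOMDEL"],
                      "y": ["WT", "SOMATIC_MUT", "WT", "HOMDEL"]})
        ctx = partition_cell_lines(garp, "x", "y", variant="ALT")
        assert (ctx.a, ctx.b, ctx.c) == (["c0"], ["c1"], ["c2"])
        # line 3, altered in both, belongs to none of the three sets

    def test_missing_context_is_not_testable(self):
        garp = _garp({"x": ["WT", "HOMDEL"], "y": ["WT", "WT"]})
        with pytest.raises(NotTestableError, match=r"\(b\)"):
            partition_cell_lines(garp, "x", "y", variant="ALT")

    def test_somatic_mutation_counts_as_wt_under_dd(self):
        garp = _garp({"x": ["WT", "HOMDEL", "WT", "HOMDEL"],
                      "y": ["HOMDEL", "SOMATIC_MUT", "WT", "WT"]})
        dd = partition_cell_lines(garp, "x", "y", variant="DD")
        # under DD the somatic mutation on y (line c1) counts as wild type,
        # so c1 lands in context (c) alongside c3
        assert (dd.a, dd.b, dd.c) == (["c2"], ["c0"], ["c1", "c3"])
        alt = partition_cell_lines(garp, "x", "y", variant="ALT")
        # under ALT line c1 is altered in both genes and is excluded
        assert (alt.a, alt.b, alt.c) == (["c2"], ["c0"], ["c3"])

    def test_variant_consistency_on_random_statuses(self):
        """Lines wild type under ALT (strictly WT) and partner homozygously
        deleted appear in context (b)/(c) under both variants."""
        rng = np.random.default_rng(0)
        codes = np.array(["WT", "HOMDEL", "SOMATIC_MUT"])
        garp = _garp({"x": list(rng.choice(codes, 30, p=[0.6, 0.2, 0.2])),
                      "y": list(rng.choice(codes, 30, p=[0.6, 0.2, 0.2]))})
        ctx = {}
        for v in ("DD", "ALT"):
            try:
                ctx[v] = partition_cell_lines(garp, "x", "y", variant=v)
            except NotTestableError:
                pytest.skip("degenerate random fixture")
        hom_y = set(garp.status.index[garp.status["y"] == "HOMDEL"])
        hom_x = set(garp.status.index[garp.status["x"] == "HOMDEL"])
        assert set(ctx["ALT"].b) & hom_y <= set(ctx["DD"].b)
        assert set(ctx["ALT"].c) & hom_x <= set(ctx["DD"].c)

    def test_contexts_disjoint(self):
        garp = _garp({"x": ["WT"] * 4 + ["HOMDEL"] * 2,
                      "y": ["WT", "WT", "HOMDEL", "HOMDEL", "WT", "WT"]})
        ctx = partition_cell_lines(garp, "x", "y", variant="DD")
        assert not (set(ctx.a) & set(ctx.b) | set(ctx.a) & set(ctx.c)
                    | set(ctx.b) & set(ctx.c))

    def test_unknown_variant(self):
        garp = _garp({"x": ["WT"], "y": ["WT"]})
        with pytest.raises(ValueError):
            partition_cell_lines(garp, "x", "y", variant="XX")


class TestGarpSlTest:
    def _fixture(self, x_scores, y_scores):
        status = {"x": ["WT"] * 4 + ["WT"] * 2 + ["HOMDEL"] * 2,
                  "y": ["WT"] * 4 + ["HOMDEL"] * 2 + ["WT"] * 2}
        return _garp(status, {"x": x_scores, "y": y_scores})

    def test_bidirectional_shift_passes(self):
        garp = self._fixture([-1, -1, -1, -1, -4, -4, 0, 0],
                             [-1, -1, -1, -1, 0, 0, -3, -3])
        ctx = partition_cell_lines(garp, "x", "y", variant="DD")
        res = garp_sl_test(garp, "x", "y", ctx)
        assert res.passed
        assert res.med_x_a == -1 and res.med_x_b == -4
        assert res.med_y_a == -1 and res.med_y_c == -3

    def test_equal_medians_fail_strict_inequality(self):
        garp = self._fixture([-1, -1, -1, -1, -1, -1, 0, 0],
                             [-1, -1, -1, -1, 0, 0, -3, -3])
        ctx = partition_cell_lines(garp, "x", "y", variant="DD")
        assert not garp_sl_test(garp, "x", "y", ctx).passed

    def test_one_sided_shift_fails_but_stats_show_asymmetry(self):
        garp = self._fixture([-1, -1, -1, -1, -4, -4, 0, 0],
                             [-1, -1, -1, -1, 0, 0, 2, 2])
        ctx = partition_cell_lines(garp, "x", "y", variant="DD")
        res = garp_sl_test(garp, "x", "y", ctx)
        assert not res.passed
        assert res.med_x_b < res.med_x_a   # x shifted
        assert res.med_y_c > res.med_y_a   # y did not

    def test_all_missing_scores_not_testable(self):
        garp = self._fixture([-1, -1, -1, -1, np.nan, np.nan, 0, 0],
                             [-1, -1, -1, -1, 0, 0, -3, -3])
        ctx = partition_cell_lines(garp, "x", "y", variant="DD")
        with pytest.raises(NotTestableError, match="missing"):
            garp_sl_test(garp, "x", "y", ctx)

    def test_missing_scores_excluded_pairwise(self):
        garp = self._fixture([-1, -1, -1, -1, np.nan, -4, 0, 0],
                             [-1, -1, -1, -1, 0, 0, -3, -3])
        ctx = partition_cell_lines(garp, "x", "y", variant="DD")
        res = garp_sl_test(garp, "x", "y", ctx)
        assert res.med_x_b == -4 and res.passed


def _pathway_tail_oracle(n, k_x, k_y, k):
    """Enumerate all C(N, K_y) annotation draws against a fixed K_x-set and
    count those sharing >= k pathways."""
    x_set = set(range(k_x))
    hits = total = 0
    for comb in itertools.combinations(range(n), k_y):
        total += 1
        hits += len(x_set & set(comb)) >= k
    return Fraction(hits, total)


class TestPathwayOverlap:
    def _ann(self, x_paths, y_paths, n):
        pathways = {f"P{i}": set() for i in range(n)}
        for i in x_paths:
            pathways[f"P{i}"].add("x")
        for i in y_paths:
            pathways[f"P{i}"].add("y")
        for i in range(n):
            pathways[f"P{i}"].add("filler")  # keep every pathway non-empty
        return PathwayAnnotation({p: frozenset(g) for p, g in pathways.items()})

    def test_zero_overlap_is_certain(self):
        ann = self._ann([0, 1], [2, 3], 6)
        assert pathway_overlap_test(ann, "x", "y").p == pytest.approx(1.0)

    def test_published_style_example(self):
        ann = self._ann(range(5), range(4), 10)
        res = pathway_overlap_test(ann, "x", "y")
        assert (res.k, res.k_x, res.k_y, res.n_universe) == (4, 5, 4, 10)
        assert res.p == pytest.approx(float(Fraction(5, 210)))

    def test_forced_complete_overlap(self):
        ann = self._ann(range(6), range(6), 6)
        assert pathway_overlap_test(ann, "x", "y").p == pytest.approx(1.0)

    @pytest.mark.parametrize("n, k_x, k_y", [(5, 3, 2), (8, 4, 3), (10, 5, 4),
                                             (12, 6, 5), (12, 9, 3)])
    def test_matches_enumeration_oracle(self, n, k_x, k_y):
        for k in range(min(k_x, k_y) + 1):
            ann = self._ann(range(k_x),
                            list(range(k)) + list(range(k_x, k_x + k_y - k)), n)
            res = pathway_overlap_test(ann, "x", "y")
            assert res.k == k
            assert res.p == pytest.approx(float(_pathway_tail_oracle(n, k_x, k_y, k)))

    def test_unannotated_gene_not_testable(self):
        ann = self._ann([0, 1], [1], 4)
        with pytest.raises(NotTestableError):
            pathway_overlap_test(ann, "x", "unknown")


class TestCallSlPairs:
    def _scenario(self, n_x=15, n_y=5):
        """A significant cluster pair where exactly one gene pair shares an
        over-represented pathway set; every other gene has one pathway."""
        xs = [f"x{i}" for i in range(n_x)]
        ys = [f"y{i}" for i in range(n_y)]
        clusters = {"CX": GeneCluster(xs, xs[0], "chr1"),
                    "CY": GeneCluster(ys, ys[0], "chr2")}
        me = MEPairResult("CX", "CY", 30, 25, 0, 0.11, 0.001, 1000)
        pathways = {f"P{i}": {"filler"} for i in range(10)}
        for i in range(5):
            pathways[f"P{i}"].add("x0")
        for i in range(4):
            pathways[f"P{i}"].add("y0")  # k=4 of K_x=5, K_y=4 from N=10
        rng = np.random.default_rng(0)
        for g in xs[1:] + ys[1:]:
            pathways[f"P{rng.integers(10)}"].add(g)
        ann = PathwayAnnotation({p: frozenset(g) for p, g in pathways.items()})
        return me, clusters, ann

    def test_single_driver_called_rest_collateral(self):
        me, clusters, ann = self._scenario()
        calls, summary = call_sl_pairs([me], clusters, None, ann)
        assert len(calls) == 1
        call = calls[0]
        assert (call.gene_x, call.gene_y) == ("x0", "y0")
        assert call.evidence == {EVIDENCE_PATHWAY}  # no GARP data provided
        labels = summary.labels[("CX", "CY")]
        assert sum(lab == "collateral" for lab in labels.values()) == 74
        assert len(call.collateral_partners) == 74

    def test_collateral_closure(self):
        me, clusters, ann = self._scenario()
        _, summary = call_sl_pairs([me], clusters, None, ann)
        labels = summary.labels[("CX", "CY")]
        assert len(labels) == 75
        assert set(labels.values()) <= {"sl", "collateral", "untestable"}

    def test_bh_adjustment_is_monotone_in_raw_p(self):
        me, clusters, ann = self._scenario()
        calls, _ = call_sl_pairs([me], clusters, None, ann, alpha=1.0)
        tested = [(c.pathway.p, c.pathway.p_adj) for c in calls if c.pathway]
        assert all(adj >= raw for raw, adj in tested)
        tested.sort()
        assert all(a1 <= a2 for (_, a1), (_, a2) in zip(tested, tested[1:]))

    def test_bh_flag_thresholds_adjusted_p(self):
        me, clusters, ann = self._scenario()
        calls_raw, _ = call_sl_pairs([me], clusters, None, ann, bh=False)
        calls_bh, _ = call_sl_pairs([me], clusters, None, ann, bh=True)
        # raw p = 5/210 passes 0.05; BH-adjusted within 75 tests does not
        assert len(calls_raw) == 1 and len(calls_bh) == 0

    def test_garp_validation_recorded_as_evidence(self):
        me, clusters, ann = self._scenario(n_x=2, n_y=2)
        status = {g: ["WT"] * 6 for g in ["x0", "x1", "y0", "y1"]}
        status["x0"] = ["WT", "WT", "WT", "WT", "HOMDEL", "HOMDEL"]
        status["y0"] = ["WT", "WT", "HOMDEL", "HOMDEL", "WT", "WT"]
        scores = {g: [-1.0] * 6 for g in status}
        scores["x0"] = [-1, -1, -5, -5, -1, -1]   # drops when y0 lost
        scores["y0"] = [-1, -1, -1, -1, -6, -6]   # drops when x0 lost
        garp = _garp(status, scores)
        calls, summary = call_sl_pairs([me], clusters, garp, ann)
        (call,) = calls
        assert (call.gene_x, call.gene_y) == ("x0", "y0")
        assert {EVIDENCE_PATHWAY, EVIDENCE_GARP_DD, EVIDENCE_GARP_ALT} <= call.evidence
        assert summary.validated_pairs == [("CX", "CY")]

    def test_unannotated_pair_falls_back_to_garp_identification(self):
        xs, ys = ["x0"], ["y0"]
        clusters = {"CX": GeneCluster(xs, "x0", "chr1"),
                    "CY": GeneCluster(ys, "y0", "chr2")}
        me = MEPairResult("CX", "CY", 10, 10, 0, 0.1, 0.001, 1000)
        status = {"x0": ["WT", "WT", "WT", "HOMDEL"],
                  "y0": ["WT", "WT", "HOMDEL", "WT"]}
        scores = {"x0": [-1, -1, -5, -1], "y0": [-1, -1, -1, -6]}
        garp = _garp(status, scores)
        calls, _ = call_sl_pairs([me], clusters, garp, None)
        (call,) = calls
        assert call.evidence == {EVIDENCE_GARP_DD, EVIDENCE_GARP_ALT}

    def test_no_data_at_all_is_untestable(self):
        clusters = {"CX": GeneCluster(["x0"], "x0", "chr1"),
                    "CY": GeneCluster(["y0"], "y0", "chr2")}
        me = MEPairResult("CX", "CY", 10, 10, 0, 0.1, 0.001, 1000)
        ann = PathwayAnnotation({"P0": frozenset({"other"})})
        calls, summary = call_sl_pairs([me], clusters, None, ann)
        assert calls == []
        assert summary.labels[("CX", "CY")][("x0", "y0")] == "untestable"
        assert summary.n_untestable == 1
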