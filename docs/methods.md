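# Methods

## Problem setting and model

Copy-number deletions in tumours are segmental: a single recombination
event removes megabases, so neighbouring genes carry nearly identical
binary deletion profiles across a cohort. Synthetic lethality (SL) between
two genes predicts mutual exclusivity of their losses across patients, but
because of segmental linkage a single true SL pair (x, y) induces apparent
mutual exclusivity between *every* neighbour of x and every neighbour of y.
The pipeline therefore (i) groups linked genes and tests exclusivity at the
group level, and (ii) resolves the driver pair within a significant group
pair with orthogonal evidence, labelling the rest collateral.

### Alteration matrix

GISTIC2 scores are binarized with `M[i,j] = 1` iff gene i is homozygously
deleted in patient j (modes `any_del` and `any_alt` cover analyses that
also count hemizygous losses or any alteration, as the broader GARP
validation variant needs). Genes altered in fewer than `min_patients`
patients are dropped; the default is 50, matching the original cohort of
6,831 patients, with `min_fraction` (0.8% ≈ the same cut) provided for
cohorts of other sizes. Exactly one of the two may be set.

### Gene distance and clustering

    D(g1,g2) = dist(g1,g2)/20 Mb + Pr(g1)·Pr(g2)/Pr(g1,g2)   (same chromosome)
    D(g1,g2) = ∞                                             (otherwise)

`dist` is the distance between transcription start sites in bp; the 20 Mb
scale is the conventional ≈20 cM equivalence. The second term is the
inverse of the observed/expected co-occurrence ratio: strongly co-deleted
neighbours approach `Pr(g)·Pr(g)/Pr(g) = Pr(g)` from above, independent
genes sit near 1, and pairs with *no* co-deleted patient are assigned ∞ —
no evidence of co-occurrence means no basis for clustering.

Clustering is affinity propagation on a precomputed similarity. "The
inverse of the distance" is ambiguous between −D and 1/D; −D is the
standard, numerically stable convention for exemplar-based message passing
and is the default, with `affinity="inv"` (1/D) available behind a flag.
Both are exposed rather than guessing the original intent. Because
cross-chromosome distances are infinite, clustering runs per chromosome —
exact under that constraint, faster, and chromosome purity holds by
construction. Within a chromosome, residual infinite distances are encoded
as a similarity one full range below the finite minimum. Hyperparameters
(damping 0.9, max 1,000 iterations, preference = median off-diagonal
similarity, fixed `random_state`) are the common defaults for the
algorithm; none are stated in the source method. Non-convergence raises an
error suggesting damping/preference changes rather than returning a silent
partial answer.

Each cluster C becomes a consensus gene: `c_C[j] = 1` iff *strictly more
than half* of the members are altered in patient j. Ties in even-sized
clusters are 0 — consensus claims an alteration only on a real majority.

### Mutual-exclusivity test

For consensus genes a, b with per-gene counts `M_a`, `M_b` and overlap
`M_ab` over `|P|` patients:

    HDMI(a,b) = (M_a + M_b − 3·M_ab) / |P|

i.e. the Hamming distance `M_a + M_b − 2·M_ab` minus the intersection,
normalised. HDMI is deliberately biased toward frequently altered genes
and can go negative under strong overlap, so it carries no universal
threshold; significance is empirical. The consensus × patient matrix is
read as a bipartite graph (edge ⇔ alteration). A null graph is generated
by `n_swaps` *attempted* two-edge swaps — a proposal that would collapse
onto an existing edge, or that shares an endpoint, is rejected but still
consumes an attempt (the source method does not say whether its 100,000
swaps count attempts or successes; attempts keep the cost fixed). This
Markov chain is symmetric over the set of 0–1 matrices with the observed
margins, so its stationary distribution is uniform on that set, which the
test suite verifies against exhaustive enumeration on a small instance.

The p-value of a pair is the fraction of null graphs with `M^i_ab ≤ M_ab`.
The ensemble depends only on the margins, so it is generated **once** per
consensus matrix and shared across all pairs; graph i is seeded
`base_seed + i`, making per-graph regeneration reproducible. Defaults are
1,000 graphs × 10·|E| swaps for desk-scale data; the original scale
(10,000 × 100,000) is a config choice away. Degenerate (all-zero)
consensus genes get p = 1 with a flag and are excluded from calls.
Raw p-values are thresholded at α = 0.05 without multiple-testing
correction across group pairs, reproducing the source procedure; an
optional add-one correction `(count+1)/(n_graphs+1)` is off by default.

Two properties of this estimator worth knowing:

* **Discreteness makes it conservative.** `M_ab` has small support, so
  P(p ≤ 0.05) sits below 0.05 (≈0.02–0.03 under the calibration conditions
  below). The mid-p transform `p − ½·P(M^i_ab = M_ab)` is uniform and is
  what the calibration check asserts (KS < 0.10, a bound covering
  Monte-Carlo noise plus the cross-pair correlation induced by sharing one
  ensemble).
* **Monotone equivalence.** For a fixed pair, p is a nondecreasing
  function of the observed overlap, so ranking by p equals ranking by
  `M_ab`.

`baseline_hypergeom` implements the naive per-pair lower-tail
hypergeometric test for comparison; it assumes homogeneous per-patient and
per-gene rates, which the worked contingency example (CTCF mutation rate
1.27% in TP53-wild-type vs 2.82% in TP53-mutant cell lines) shows to be
false.

### SL calling

Within a significant cluster pair (X, Y), all |X|·|Y| gene pairs are
evaluated:

* **Pathway overlap** (identification): genes x and y annotated to K_x and
  K_y of N pathways share k; the upper-tail hypergeometric
  P(overlap ≥ k) under independent annotation is the test. The universe N
  is the annotation restricted to analysed genes, so pathways no analysed
  gene can hit do not dilute the test. Benjamini–Hochberg adjustment is
  computed within each cluster pair and always reported; *thresholding*
  uses raw p < α by default, matching the source results (which threshold
  raw p at 0.05 and quote adjusted values descriptively). With `bh=True`
  the adjusted value is thresholded instead.
* **GARP essentiality shift** (validation): cell lines are split into
  (a) both wild type, (b) x WT / y altered, (c) x altered / y WT; lines
  altered in both are excluded. "Altered" is HOMDEL under variant `DD`, or
  HOMDEL ∪ SOMATIC_MUT under `ALT` (under `DD` a somatically mutated line
  counts as wild type). The pair passes iff median GARP of x on (b) <
  on (a) **and** median of y on (c) < on (a), both strictly — equal
  medians carry no directional evidence. Missing scores are excluded
  pairwise from medians, never imputed. Any empty context makes the pair
  *not testable* for that variant; `min_context` (default 1, faithful to
  the source) can floor the context sizes.

A gene pair is **called SL when the pathway test passes**; GARP passes are
recorded as `GARP_DD`/`GARP_ALT` evidence, and a cluster pair is
"validated" when some gene pair carries both channels. When a pair has no
pathway annotation at all, a GARP pass identifies on its own (each channel
substitutes for the other's absence, never for its failure). This
pathway-primary reading is deliberate: the two-sided strict median
comparison passes by chance for roughly a quarter of null pairs, so a rule
in which a lone GARP pass creates a call would bury the driver in
passenger calls in any cohort; the source workflow likewise identifies by
pathway overlap and validates with GARP. Every gene pair in a significant
cluster pair ends up labelled exactly one of SL-called / collateral /
untestable, and each call lists its cluster pair's collateral pairs.

## Synthetic cohorts

The generator's defaults are the study conditions used throughout the
tests: 500 patients; 4 chromosomes × 5 segments × 5 genes (100 genes,
TSS spacing 100 kb within a segment, 30 Mb between segments); per-segment
deletion rate 0.10 with ±25% jitter; within-segment co-deletion 0.95;
gene-level background deletion 0.005; patient propensity a two-point
mixture (0.6 w.p. 0.7, 1.93 w.p. 0.3, mean 1) recreating heterogeneous
per-patient burdens; one planted driver segment pair on different
chromosomes with joint deletion probability ε·(product of marginals),
ε = 0.05; non-deleted entries get sporadic −1/+1/+2 scores so binarization
is exercised. The matched GARP screen uses 50 cell lines drawn from the
same cohort model (baseline −1, noise sd 1, somatic mutation rate 0.05)
with the driver pair's scores shifted down by Δ = 3 in partner-altered
lines; the matched annotation plants k = 4 shared of K_x = 5 / K_y = 4
draws from N = 10 pathways (raw p = 5/210), with background genes
annotated to 1–2 pathways (second pathway w.p. 0.3 — a sparse-annotation
regime in which chance overlaps of small annotation sets rarely reach
significance). All randomness flows from one master seed via SeedSequence
spawning (stream 0 cohort, 1 GARP, 2 pathways).

Deletions are simulated at *segment* level so neighbour correlation is
structural, exactly the mechanism that motivates clustering. What the
generator does **not** emulate: focal (sub-segment) deletions, arm-level
events spanning several segments, amplification-driven SL, correlated
GARP noise across cell lines, or realistic pathway-size distributions.
Passing recovery tests therefore demonstrates correctness of the machinery
under the stated generative assumptions, not performance on TCGA-scale
data — reproducing the original cohort's tallies (660 clusters, 285 DDR
pairs, the 73–81% GARP validation rates) requires the external TCGA /
essentiality-screen / pathway downloads and is out of scope.

## Numerical and design notes

* Problem sizes in the tests — 1,000-graph nulls, 10·|E| swaps, cohorts of
  100–200 genes — are the package's desk-scale defaults; estimates at
  these sizes are within Monte-Carlo error of the enumeration oracles, and
  the original scale is reachable through config alone.
* The swap-vs-enumeration check uses 500 swaps per graph on its 12-edge
  instance: the 3-standard-error comparison presumes stationarity, and
  extra mixing on a tiny graph is cheap.
* The edge-swap inner loop is JIT-compiled (numba) over the boolean
  incidence matrix; duplicate edges are impossible in that representation,
  and degree preservation is asserted in tests on every randomization.
* Significance thresholds are strict (`p < α`), following "p value lower
  than 0.05"; a pair at exactly p = 1 is never significant even at α = 1.
* Coordinates are 1-based internally; BED input converts from 0-based
  half-open as start+1 on the plus strand and end on the minus strand.
* Duplicate gene rows in CNA input error by default (`"first"` keeps the
  first occurrence and counts the drop); all dropped or modified records
  are tallied in per-file load reports.
* `filter_genes` with everything below threshold errors, advising a lower
  threshold, rather than returning an empty analysis.

## Known limitations

* Empirical p-values are lower-bounded by 1/n_graphs; pairs reported at
  p = 0 mean "below resolution", and the optional add-one correction
  bounds them away from zero at the cost of exact source fidelity.
* No multiple-testing correction across cluster pairs (faithful to the
  source); with thousands of cluster pairs, expect α-level false
  positives among significant pairs.
* Affinity propagation can fail to converge on adversarial similarity
  structures; the error message exposes damping/preference as the knobs.
* The GARP median test has no significance calibration of its own — it is
  a directional filter, which is why it validates rather than identifies
  when pathway data exist.
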