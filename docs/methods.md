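# Methods

This note documents the models, defaults, and numerical choices behind
`vrcall`, and what the synthetic-data tests do and do not establish about
real data.

## Preprocessing

QC is computed on raw counts: `n_genes` (genes with count > 0),
`total_counts`, `pct_mito` (percent of counts in mitochondrial-class
catalog genes), and `hbb_positive` (any count in a hemoglobin-class
gene). Filtering keeps cells with `200 ≤ n_genes ≤ 7000` (closed
interval — the natural reading of the range), drops hemoglobin-positive
cells (red-blood-cell contamination; any-count positivity is the
strictest reading and is configurable to a normalized-expression cutoff),
and drops cells with `pct_mito > 20%`. The mitochondrial rule is a
deterministic per-cell approximation of removing a mitochondria-enriched
cluster; clustering itself is out of scope here, and the cutoff is
configurable.

Normalization is LogNormalize: `x(c,g) = ln(1 + s · count(c,g) / T(c))`
with scale factor `s = 10,000`. Natural log with pseudocount 1 keeps
zeros at exactly zero and preserves within-cell rank order. Ambient-RNA
correction is not performed; instead the thresholding stage is designed
to be robust to ambient contamination, and the simulator injects ambient
counts to exercise exactly that.

Marker-based cell typing uses normalized expression against a single
cutoff (default 1.0): Gap43 above the cutoff marks immature neurons
(split by the dominant G-protein marker), Ascl1/Neurod1 mark progenitors,
Gnao1 xor Gnai2 marks the two mature types, both together yields
`ambiguous` (a doublet signature), anything else `other`. Externally
supplied labels (e.g. from a full clustering workflow) pass through
verbatim and are the recommended input when available.

## Threshold derivation

For each receptor family (V1R; all V2R subfamilies pooled; H2-Mv) the
nonzero normalized values of all family genes over a cell subset are
pooled — one value per (cell, gene) pair. Exact zeros are excluded: the
zero point mass carries no information about where true expression
begins and would dominate any density estimate. The default cell subset
is the mature neurons; it is a parameter because the appropriate
reference population may differ by experiment.

The cutoff is the density valley between the ambient mode and the
expression mode:

1. **Mode detection.** Gaussian KDE with Silverman's bandwidth on a
   512-point grid. The two highest-density modes separated by at least
   `min_separation` (default 0.2 normalized units) qualify, with two
   guards against spurious modes: the second mode must reach ≥ 5% of the
   main mode's density, and the density between the two must dip below
   90% of the smaller of them. If no qualifying pair exists, the
   configured default threshold is returned with `fallback_used=True`.
2. **Valley location.** The threshold is the density argmin, between the
   two detected modes, of a two-component Gaussian mixture fitted to the
   pooled values (EM, 2 initializations, fixed seed). A parametric
   mixture is used for the valley rather than the KDE itself because a
   single global bandwidth systematically oversmooths mixtures whose
   ambient component is much narrower than the expression component,
   biasing the KDE valley toward the wide component by several tenths of
   a unit; the mixture valley is unbiased in that regime (verified
   against the analytic density minimum of a known mixture in
   `tests/test_acceptance.py`, max error < 0.01 at n = 10,000). If the
   mixture fit degenerates (both components on one mode), the KDE valley
   between the detected modes is used instead.

Pinned mode (`mode="fixed"`) sets V1R = 2.5 and V2R = H2-Mv = 1.25, the
conventional cutoffs for this tissue, and is the right choice when
reproducing a reference analysis exactly.

## Receptor calling and patterns

A gene is called expressed iff its normalized value **strictly** exceeds
the family threshold — ties at the threshold are not calls, making the
boundary deterministic. Cells with no calls are retained (they populate
the k = 0 bin of the per-cell histograms and are biologically
meaningful: stringent thresholds leave some genuine neurons with zero
called receptors).

Patterns are exact called-gene sets per cell, counted over cells within
a scope (single family, or cross-family such as ABD×C×H2-Mv where genes
carry family tags). A cell calling {A, B, C} contributes to the
{A, B, C} pattern only, not to its subsets; subset counting would make
the row counts non-additive and is intentionally not implemented. Rows
with fewer than `min_cells = 2` cells are dropped: the probability that
the same doublet-induced combination arises twice is very low at
realistic doublet rates, so recurrence is the doublet filter. `min_cells`
is exposed as a flag.

Dosage analysis sums the normalized expression of called family genes
per cell and reports medians and quartiles by k (number of called
members), alongside the same statistics for a control gene (Gnao1 or
Gnai2). Proportional scaling of the family total with flat control is
the signature of true multi-receptor expression; a doublet would scale
both.

Gnao1 subtype classes: `C1` (C1 called, no C2), `C2_H2Mv_pos`/`C2_H2Mv_neg`
(C2 called, split by H2-Mv), `C_none` (no family-C call). Cells calling
both C1 and C2 — a rare but real configuration (e.g. Vmn2r1 + Vmn2r7) —
default to a separate `mixed` class; a configurable rule can fold them
into either branch. The summary reports the fraction of family-C callers
without any H2-Mv call.

## Differential expression and ORA

Per-gene two-sided Wilcoxon rank-sum between two disjoint groups of ≥ 3
cells. For group sizes ≤ 10 the p-value is the exact permutation tail
(full enumeration of group assignments, valid under ties); otherwise the
tie-corrected normal approximation with continuity correction. The two
branches agree within a few percent away from the extreme tail; in the
tail the normal approximation is relatively coarse, which is exactly why
the exact branch exists where enumeration is feasible.

Only genes detected in ≥ `min_pct` (default 1%) of either group are
tested; Bonferroni adjustment runs over the tested genes. Fold change is
computed on de-logged normalized means with pseudocount 1:
`log2FC = log2((mean(expm1 x_A)+1)/(mean(expm1 x_B)+1))`. Significance
combines `|log2FC| > 1` with adjusted `p < 1e-6`; the adjusted-p
criterion is applied throughout (a raw `-log10 p > 6` axis convention
exists in some visualizations; the adjusted criterion is the stricter
and is the one used here).

Over-representation is the upper-tail hypergeometric probability of the
observed overlap between a query list and each gene set, both intersected
with a stated universe (the tested genes). Gene-set databases are not
bundled or downloaded — database-version-dependent term lists are not
reproducible — sets are supplied as GMT.

## Axis profiles

Each ROI is normalized independently (per-ROI min-max on the position
axis and every channel), position 0 = apical, 1 = basal. Trendlines pool
points from all sections and fit a locally weighted linear regression
(tricube weights, span = fraction of points per local fit, default 0.5)
evaluated on a 101-point grid. A LOESS smoother is used as the
smooth-trend mechanism because it has a single interpretable tunable;
any smooth-trend fit (e.g. a penalized spline GAM) serves the same
contract. Co-trending of two channels is the Spearman rank correlation
of their fitted curves on the common grid.

## The synthetic-data generator

`SimConfig` defaults define the study conditions used by the tests and
the acceptance script:

| parameter | default | rationale |
|---|---|---|
| cells | 1000 mature Gnao1, 2000 mature Gnai2, 400+400 immature, 400 progenitor, 800 other | ≈ 64% neuronal mix with ≈ 1000 Gnao1 neurons, the composition the analysis is designed for |
| panel | 150 V1R, 70 ABD, 1 C1 + 6 C2, 6 H2-Mv, 1000 background, 50 ER | loose mirror of the mouse repertoire at desk scale |
| `on_mean` / `ambient_mean` | 25 / 0.05 | true expression vs rare stray ambient counts; produces the assumed bimodality of pooled normalized values |
| `dispersion` | 0.15 | negative binomial var = m + 0.15 m², mild scRNA-seq overdispersion |
| library size | lognormal, sd 0.3 | per-cell depth variation |
| `p_C1_vs_C2` / `p_H2Mv_given_C2` | 0.4 / 0.7 | planted H2-Mv-negative fraction among family-C callers = 0.4 + 0.6·0.3 = 0.58 |
| C2 members / H2-Mv members | uniform 2–6 / 1–4 | the observed combinatorial ranges |
| planted ABD exceptions | Vmn2r20+22 at 4.3%, Vmn2r39/43/50 at 1% | recurring multi-ABD combinations at realistic frequencies |
| `er_log2fc` | 2 | ER-gene upregulation in mature Gnao1 cells |
| `doublet_rate` | 0 (0.01 in contamination studies) | doublets sum two random cells' counts |

Markers have zero ambient mean (well-separated marker levels), so
marker-based classification is near-perfect on simulated data — by
construction. Counts are negative binomial; no UMI chemistry, batch
effects, or cross-sample depth normalization are emulated.

**What passing tests show, and what they do not.** The simulator
reproduces the *assumptions* of the analysis (bimodal ambient/expression
separation, independent planted combinations, NB noise). Passing
recovery tests therefore demonstrates that the implementation correctly
inverts its own model at realistic sizes — not that the model captures
every property of real droplet data (correlated ambient profiles,
partial doublets, zone-dependent capture efficiency are not modeled).
On simulated data the detected thresholds (~2.8–3.0) differ from the
conventional 1.25/2.5 because the simulated ambient mode sits higher
than in real data; the valley logic, not the absolute value, is what the
tests validate, and pinned thresholds are available for exact
reproduction of a reference analysis.

## Problem sizes and determinism

The acceptance battery uses n = 10,000 values × 20 seeds for threshold
recovery, the 5,000-cell default simulation (with 1% doublets) for
calling/patterns/dosage/subtypes, and 20 seeds of 1,050 genes × 400
cells for DE calibration — sizes at which the binomial error of the
measured rates is well inside the asserted bounds. Every random draw
flows from `numpy.random.default_rng(seed)`; the same config and seed
give bit-identical datasets, and the pipeline's outputs are pure
functions of inputs and config (byte-identical across reruns).

## Known limitations

* Clustering, UMAP, pseudotime, and ambient-RNA correction are upstream
  concerns; supply external labels for real analyses.
* Exact-set pattern counting does not credit supersets to subset
  patterns (documented above).
* The per-cell mitochondrial cutoff approximates cluster-level removal.
* The Wilcoxon normal approximation is coarse in the extreme tail for
  moderate group sizes (the exact branch covers sizes ≤ 10).
* ORA treats gene sets as unordered; no ranked (GSEA-style) statistic.
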