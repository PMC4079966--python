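# Methods

This note records the models, parameter choices and numerical conventions
behind `replitime`, and what the synthetic-data tests do and do not
establish about real data.

## Signal extraction

Reads are placed by their 5′-most aligned base (strand-aware). The paper's
analysis environment leaves the placement rule open; the 5′ convention is
the common short-read choice and makes counting exactly reproducible. On
sliding grids (5-kb windows, 1-kb step) a read contributes to every window
containing its 5′ base; window width must be a multiple of the step so the
rolling-sum implementation is exact. All coordinates are 0-based half-open.

RPKM divides counts by bin length (kb) and library size (millions of mapped
reads); the library size is the fraction's total mapped reads, not the
in-grid subset. Because RPKM hides per-chromosome coverage differences in
aneuploid lines, the segmentation input is additionally *divided* by each
chromosome's mean RPKM over all four fractions. Division (not
multiplication) is what gives each chromosome proportional representation;
the inverse weighting is retained as `normalization_mode="multiply"` for
comparison. Percentile capping replaces values above the per-fraction
genome-wide 95th percentile (linear interpolation between order statistics,
the R default) with that percentile; capping is idempotent exactly when the
percentile lands on an order statistic, and up to interpolation otherwise.

## Timing score

The score s = (w·x)/Σx with w = (0.125, 0.375, 0.625, 0.875) is the convex
combination of quarter-midpoints weighted by fraction abundance; it is
scale-invariant (hence library-size invariant), bounded by [0.125, 0.875]
with the bounds attained only under single-fraction support, and undefined
where all fractions are zero. Orientation: the latest fraction maps to
0.125 and the earliest to 0.875, so high scores mean early replication —
the self-consistent reading of the source material's description.

Smoothing is a plain loess: for each 10-kb bin midpoint, a tricube-weighted
degree-2 polynomial is fitted to the k nearest scored bins, with
k = window/bin-width (200 kb / 10 kb = 20, floored at 4). The implementation
matches R's `loess` (`surface="direct"`, gaussian family) to ~1e-13 on test
data; it is written in-package because the available Python lowess fits only
degree-1 local models. Missing bins are imputed from the local fit;
chromosomes with fewer than 4 scored bins pass through unsmoothed with a
warning. Smoothed values are clipped to the theoretical score range by
default (`clip=False` to disable) — whether the published profiles clipped
is unknowable from the text, so it is toggleable.

The log₂ timing ratio uses only the earliest and latest fractions (the
mid fractions largely parallel them), with a pseudocount defaulting to the
5th percentile of nonzero E/L RPKM to keep ratios finite without crushing
dynamic range.

## HMM segmentation

Three states (early, late, indeterminate) emit bivariate normals over the
normalized-capped (E, L) signal. The normalized-capped signal — rather than
raw RPKM — is used as the observation because normalization and capping are
described as preparation for domain calling.

* **Initialization.** k-means (k = 3, 10 restarts, fixed seed recorded in
  the model sidecar) on the 1-D log₂(E/L) ratio; each cluster's member
  windows supply one state's empirical bivariate mean and covariance.
  Clusters are ordered by mean ratio (late, indeterminate, early).
  Transitions start at self-probability 0.998 (off-diagonal split equally):
  the exact published value is unstated, and 0.998 makes the expected
  initial run length (~500 windows ≈ 500 kb) commensurate with domain
  scale. Initial state probabilities are uniform.
* **Training.** Per chromosome, scaled forward-backward Baum-Welch until
  Δlog L < 0.05 (cap 500 iterations, warned). Covariance M-steps project
  onto {Σ : eigenvalues ≥ ε} with ε = 10⁻³ × the mean per-channel variance
  of that chromosome's observations, fixed for the whole run. This is the
  constrained maximizer of the Gaussian likelihood, so the EM ascent
  guarantee survives; without it the early channel of the late state (which
  is almost exactly zero) collapses the covariance and the likelihood
  diverges. Incoming models are projected into the same set before the
  first iteration. `tol=inf` performs exactly one EM sweep.
* **Labeling.** After training, states are re-ranked by emission mean
  difference (mean E − mean L): top = early, bottom = late, middle =
  indeterminate. Labels are semantic; training may permute state indices.
* **Decoding.** Viterbi in log space; ties break deterministically toward
  the lower state index. Per-window posteriors (forward-backward) provide
  each domain's score as the mean posterior of its assigned state.
* **Run merging.** Runs shorter than 40 windows are merged iteratively:
  always the globally shortest sub-threshold run first (leftmost on ties),
  relabeled to the longer flanking run (left wins length ties; a
  single-flank rule applies at chromosome ends), re-scanned after each
  merge. A sub-threshold run spanning a whole chromosome is kept. The order
  of merging is not specified in the source; shortest-first is
  deterministic and minimizes label churn.
* **Domains.** Each 1-kb step carries its window's label; a maximal run
  over steps i..j becomes [startᵢ, startⱼ + step). The window/step overhang
  means the final window-width−step of each chromosome is uncalled.

## Cross-line classification

Position-level on the 1-kb step grid: early in all samples → static early;
late in all → static late; early in ≥1 and late in ≥1 → dynamic; anything
else (an indeterminate call without conflict, or positions uncovered by a
sample) → indeterminate. A position-level rule was chosen over
reciprocal-overlap interval intersection because genome *fractions* are the
quantity of interest and the rule defines them unambiguously; fractions are
reported over the full assembly grid and sum to 1. The rule is symmetric in
sample order, and adding a sample can only move positions toward dynamic or
indeterminate.

The per-chromosome comparison uses a two-sided Mann-Whitney U test of the
target chromosome's 10-kb timing values against the pooled background; the
test is unnamed in the source, and the standard rank test matches the
"p < 2.2e-16" floor-reporting convention of its analysis environment.

## Annotation

Feature membership is by start position (not any-overlap), which makes
densities additive over disjoint regions; density = count/length × 10⁵
(per 100 kb). Track summaries are bp-weighted medians of the genome-wide
normalized track over each region; the default normalization is a
length-weighted z-score per track (z of a constant track is 0 by recorded
convention), with a bp-weighted quantile transform available for
cross-platform tracks — the exact normalization used for published
"normalized expression" panels is unstated, so it is a config choice.
Difference-ratio layers are elementwise log₂((a+ε)/(b+ε)) with ε recorded
(sensible for non-negative normalizations). The timing-ordered matrix sorts
10-kb bins ascending by score, ties broken by (chromosome, start).

## Synthetic data

The generator emulates the study design: a multi-chromosome genome tiled by
early/late domains; per-domain true time t drawn uniformly from [0.75, 1]
(early) or [0, 0.25] (late); per-10-kb-bin Poisson totals with mean
`mean_reads_per_bin × copy_number`; multinomial apportionment across
fractions with p_k(t) ∝ exp(−κ(t − m_k)²), m_k the quarter midpoints. This
family is the minimal smooth, symmetric model under which the weighted
score is an approximately unbiased estimator of t, and κ = 0 degenerates to
uniform quarters. Reads are 50-bp single-end + strand intervals uniform
within their bin; domain boundaries sit on the 10-kb bin lattice so bins
never straddle a boundary.

Defaults (chosen once, as the study conditions the tests assume): 20-Mb
genome as four 5-Mb chromosomes; domains 100–500 kb; early fraction 0.5
(greedy label assignment keeps the achieved fraction within one domain of
the target); 100 reads per 10-kb bin; κ = 20, at which a bin at t = 0.95
puts ~88% of its reads in the early fraction; TSS densities 10 vs 2 per
100 kb (early vs late) and ORC 6 vs 1, mirroring the strong early-domain
enrichment of promoters and origins. `perturb_truth` flips a random domain
subset covering a requested genome fraction (resolution ~half a domain) to
plant dynamic regions for a derived cell line.

Not emulated: sequencing error, mappability variation, GC bias,
overdispersion beyond Poisson, replicate structure, within-domain timing
gradients, and the FACS gating process. Consequently the recovery tests
demonstrate algorithmic correctness and calibration under the stated noise
model — they do not certify performance on real libraries, where
overdispersion and mappability artifacts widen boundary error and inflate
the indeterminate state.

## Problem sizes and tolerances in the test battery

Exact dynamic-programming checks compare Viterbi against exhaustive
enumeration on 200 random models with sequences of ≤8 windows; EM ascent is
asserted with slack 10⁻⁸ over every training run; parameter recovery uses
10⁴ bins from a well-separated 3-state HMM (means within 10%); end-to-end
recovery uses the default 20-Mb study (≥95% position accuracy, median
boundary error ≤10 kb); score algebra is checked on 10⁶ random vectors; the
static/dynamic experiment uses three simulated lines with a 10% planted
switch fraction (recovered within 2 percentage points). The acceptance
script (`scripts/acceptance.py`) recomputes all of these from a single seed.

## Known limitations

* The loess evaluator is O(n·k) per chromosome and loops in Python; fine at
  10-kb resolution, slow if applied to the 1-kb grid.
* Baum-Welch forward/backward recursions loop over positions in Python;
  ~1 s per 5-Mb chromosome per training run at the default tolerance.
* `median_signal` iterates regions per track; suitable for thousands of
  domains, not millions of windows.
* Indeterminate calls on clean synthetic data are rare by construction; the
  indeterminate state's behaviour under realistic mid-S signal (gradual
  boundaries, partial replication) is untested here.
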