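# Methods

## Colocalization scoring

A tumor section is a marked point pattern: cell centroids in μm with a
class label in {cancer, immune, stromal_other}. The analysis window is the
pattern's bounding rectangle unless supplied explicitly.

**Square tessellation.** The window is tiled with axis-aligned squares of
side `s` (default 250 μm), anchored at the window's minimum corner; the last
row/column is clipped, so the polygons always partition the window exactly.
Cells are binned with half-open intervals `[lo, lo + s)` so every cell maps
to exactly one square; a cell landing exactly on the window's maximum edge
is kept in the last row/column rather than lost. The 250 μm default follows
the scale of effective cell–cell communication; `{100, 250, 500, 1000}` μm
is the conventional sensitivity sweep.

**Voronoi tessellation.** Generator points are sampled uniformly in the
window (fixed, recorded seed) and their Voronoi cells are clipped to the
window. When used inside the scoring pipeline the generator count is set to
the section's number of occupied 250 μm squares, keeping polygon density
comparable across tessellation kinds. Cell-to-polygon assignment uses the
nearest generator, which coincides with point-in-polygon containment except
on measure-zero boundaries.

**Tissue filter.** Polygons with total cell count `t_i` (all three classes)
below `min_cells` (default 10) are excluded before any index is computed.
The threshold is a count, not an area, so it is resolution-independent.
Stromal/other cells contribute to `t_i` only — the indices are defined on
cancer and immune cells.

**Indices.** Morisita–Horn as in the README formula; Pearson is the
product-moment correlation of the paired per-polygon counts. Degenerate
inputs (fewer than two polygons, an absent class, zero variance) yield a
missing value with a warning, never a number. Multiple sections of one
patient are combined by pooling their retained polygons into one count
table before computing the indices (default); a per-section-mean strategy
is selectable, and the choice is recorded in the score's provenance.
Pooling was preferred because it maximizes the number of sampling units and
is exactly invariant when sections are statistical replicates (the index's
scale invariance makes pooling duplicated tables a no-op).

## Survival protocol

- Dichotomization is strict: high means score **>** cutoff; ties go to low.
- The cutoff search evaluates score percentiles 20, 21.5, …, 80 (41
  candidates; linear-interpolation percentile definition), dichotomizes at
  each, and keeps the candidate with the smallest log-rank p. Exact ties
  are broken toward the cutoff closest to the median score (the more
  balanced split). Candidates leaving a group empty are skipped.
  "Most prognostic" is interpreted as smallest p rather than largest
  effect size.
- The chosen cutoff is frozen before any validation-cohort quantity is
  computed; stratified analyses learn their cutoff on the discovery subset
  of the stratum only. Frozen reference cutoffs from the original
  breast-cancer calibration are shipped in
  `ecoloc.survival.REFERENCE_CUTOFFS` for scoring comparable data.
- The log-rank test is the standard observed-minus-expected form with
  hypergeometric variance (1 df). It is implemented directly in numpy
  because the cutoff search and the Monte-Carlo calibration tests evaluate
  it ~10⁵ times; the implementation is cross-checked against lifelines to
  9 decimal digits in the test suite.
- Cox models use lifelines (Efron tie handling, Wald 95 % CIs). The
  multivariate set is {score group, lymph-node status, tumor size, grade};
  size and grade enter as ordinal codes. Rows missing a covariate are
  dropped from that model only. Age is excluded by default (exposable as an
  optional covariate). Non-convergence or separation is flagged in the
  result object, never silently reported.
- All follow-up is administratively censored at 120 months (10-year
  disease-specific survival); the preprocessing step truncates any longer
  time and converts its event to a censoring.
- Bootstrap robustness draws ⌈fraction·n⌉ patients **without replacement**
  per replicate (the sampling scheme implied by taking a percentage of
  patients) and reports the share of usable replicates with log-rank and
  multivariate-Cox p < 0.05; replicates with no events or a one-sided split
  are counted separately.
- Tissue subsampling re-scores spatially contiguous vertical slabs
  containing 75/50/25 % of the retained polygons (10 sweep offsets;
  a random-subset mode exists) and reports spread against the full-slide
  value.

## Association tests

Jonckheere–Terpstra is hand-implemented (no scipy/statsmodels equivalent):
J sums Mann-Whitney counts over ordered group pairs with ties counted ½;
p-values use the tie-corrected normal approximation, switching to exact
enumeration of the group-assignment null for n ≤ 12 (two-sided by deviation
from the null mean). Fisher's exact test delegates to scipy's
probability-mass two-sided rule (log-space hypergeometric, so p ≈ 1e-37 is
representable), with a zero margin returning p = 1 under a warning.
Kruskal–Wallis delegates to scipy's tie-corrected H; an all-tied input
returns H = 0, p = 1 instead of an error.

## Synthetic data

**Patterns.** A Thomas-type cluster process. Poisson(κ·A) cancer parents
are placed uniformly; each receives Poisson(μ_c) cancer offspring and
Poisson(ρ·μ_i) immune offspring, displaced by isotropic Gaussian noise
(sd σ). An independent set of immune-only parents carries the remaining
Poisson((1−ρ)·μ_i) immune offspring per parent. Offspring are reflected at
the window boundary. Stromal cells are a uniform background sized so they
form the configured fraction of all cells in expectation. ρ is therefore a
pure colocalization dial: at fixed κ, μ_c, μ_i the marginal intensities of
both classes are constant while the shared-parent fraction moves from 0 to
1, and the mean Morisita index rises monotonically with it (verified over
100 replicates per level in the acceptance suite).

Defaults — 2000 × 2000 μm window, κ = 5·10⁻⁶ parents/μm², μ_c = 100,
μ_i = 50, σ = 60 μm, 30 % stromal — give ≈ 4–5 thousand cells and an 8 × 8
grid of 250 μm squares per section. This is a deliberately compact stand-in
for whole tumor sections (tens of thousands of cells); it reproduces the
clustered two-class geometry the indices consume, not the cell counts of
full slides, so results at this scale say nothing about segmentation error,
staining artefacts, or classifier noise in real images.

**Survival.** Weibull baseline hazard (default shape 1, i.e. exponential,
scale 1200 months) with linear predictor
β·1[ρ > ρ\*] + log(2.0)·node + log(1.6)·size-step + log(1.6)·(grade−1);
β defaults to log 0.5 and ρ\* to 0.5. The step link from ρ to hazard gives
the cutoff search a recoverable ground truth. The baseline scale was set so
the simulated cohort's 10-year event fraction is ≈ 25 % once the covariate
mix is applied, matching an unselected breast-cancer cohort with
near-complete 10-year follow-up; censoring is accordingly administrative at
120 months for most patients with a 20 % minority censored Uniform(0, 120)
(early loss to follow-up). Covariate marginals (grade, node, size, ER,
Her2, PAM50, treatment flags) are drawn from frequencies typical of such a
cohort.

**Seeding.** One global seed feeds a `SeedSequence` that spawns one
substream per patient (and per section), so any patient's pattern can be
regenerated in isolation and results are stable under re-ordering.

## Monte-Carlo test conditions

The calibration checks run at sizes chosen to give stable verdicts in
seconds: log-rank type-I error on 1000 null replicates of 2 × 100 patients
(3σ binomial band around 0.05); Cox CI coverage of a true HR 0.4 on 200
replicates of n = 500; change-point recovery on 100 replicates of n = 400
with HR 0.25 and ≈ 30 % ten-year events in the unprotected group —
comparable to the event fraction of a low-colocalization stratum. Recovery
is judged against the realized sample percentile of the generative
change-point (its rank in the drawn scores), which is the quantity the
search can in principle find; the nominal population percentile differs
from it by sampling jitter (sd ≈ 2.5 points at n = 400) that is not
attributable to the estimator.

## Known limitations

- The minimum-p cutoff estimator is biased toward optimistic discovery
  p-values by construction; only the frozen-cutoff validation quantities
  should be read as confirmatory.
- Voronoi scoring uses random generators, not density-adaptive ones; the
  recorded seed makes it reproducible but a different seed gives a slightly
  different score.
- No competing risks, time-varying covariates, or formal proportionality
  diagnostics (a warning hook only).
- The generator does not model classifier error, section-to-section
  heterogeneity within a patient (sections share one ρ), or anisotropic
  tissue architecture.
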