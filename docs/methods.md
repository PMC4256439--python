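# Methods

## Measurement model

Both assays are analysed as two-level hierarchical Gaussian models.  A
well-level measurement of sample *s* on plate *j* is

    y_sij = mu_s + b_sj + e_sij,      b_sj ~ N(0, sigma_inter²),
                                      e_sij ~ N(0, sigma_intra²)

For the deletion assay, `y` is the percent of deleted mtDNA and both SDs
are in percentage points.  For the copy-number assay the model holds on
the natural log of the MT-ND1/B2M ratio, so `sigma_intra` and
`sigma_inter` are geometric SDs and `exp(sigma)` is the multiplicative
"scale factor" (a GSD of 0.0686 means a ±7.1% one-SD band).

The plate effect `b_sj` is drawn **per sample per plate** and shared by
all of that sample's replicate wells on the plate.  This is a deliberate
choice over a single plate-wide effect: a shift common to every sample on
a plate would cancel exactly in any between-sample comparison, whereas the
between-plate variability this package quantifies is precisely the
component that survives in such comparisons (plate-to-plate variation in
how a given sample reads out).  A plate-wide calibration shift is real in
raw Cq space but is removed by the standard curve and, for copy number, by
reference normalisation, so it is not modelled at measurement level.

The Gaussian form is an assumption, not an empirical finding; it is the
conventional choice for replicate qPCR estimates after log/percent
transformation and is what the c4 bias correction and the noncentral-t
power theory presuppose.

### Intra-plate SD model (simulator)

Deletion mode: `sigma_intra(p) = a + b·p`, clamped at 0, with defaults
`a = 3.398`, `b = −0.03415` (percentage points per percent heteroplasmy).
These reproduce the characterised high-concentration values
`sigma_intra(10) ≈ 3.06` and `sigma_intra(90) ≈ 0.32` obtained by
decomposing the 3-replicate per-plate SD column (1.83 … 0.52 points)
against the pooled inter-plate SD of 0.485 points.  Precision collapses at
low template input: when the run's mean Cq exceeds 30 cycles the SD is
multiplied by `cq_inflation` (default 3), a step change standing in for
the empirically exponential growth of error past that threshold.

Copy-number mode: geometric SDs per concentration level — 0.0686 (high),
0.0834 (moderate), 0.181 (low) — with a between-pair geometric SD of
0.0305.  Concentration levels map to mean Cq values of 19/27 (MT-ND1/B2M,
high), 24/30 (moderate) and 25.5/33 (low); the B2M reaction runs an order
of magnitude more concentrated to keep nuclear Cq inside the optimal
17–33 window.

### Default study designs

The simulator's factory designs mirror the characterisation experiments:
six single-deletion samples (84, 69, 48, 38, 20, 6% deletion) in 84
replicates per concentration on one plate; six mixture samples (20, 22.5,
25% and 70, 75, 80% deletion) in 24 replicates on each of 3 plates; five
copy-number samples at relative levels 1, 1.10, 1.25, 1.50, 1.9 in 12
replicates per plate pair on 4 pairs.

### What the simulator does not model

No molecule-level PCR stochasticity (branching-process amplification), no
pipetting-volume error, no well-position or plate-edge effects, no
inhibitor effects.  Passing recovery tests therefore show that the
estimators are correct for the assumed error structure, not that real
plates obey it; with real data the severe-outlier filter is the only
guard against structure the model lacks.  Deletion values are clipped to
[0, 100]; for truths in [20, 80] with sigma_intra ≤ 3 the excursion
probability is below 1e-8, so the clipping bias is negligible except at
very low or very high heteroplasmy, where it slightly shrinks the SD.

## Estimation

* **Severe outliers**: points beyond 3×IQR below Q1 or above Q3 are
  removed once per sample × plate group before any estimation.  Quartiles
  use linear interpolation between order statistics (the common "type 7"
  convention; configurable).  The filter is single-pass by design —
  fences are never recomputed from filtered data.
* **Intra-plate SD**: sample SD (n−1) divided by the Gaussian
  bias-correction factor `c4(n) = sqrt(2/(n−1))·Γ(n/2)/Γ((n−1)/2)`
  (log-gamma evaluation).  Across plates, per-plate SDs are pooled as a
  df-weighted root mean square.  Bootstrap percentile intervals
  (default B = 10,000, floor 1,000; seeded) give 95% CIs.
* **Inter-plate SD**: the SD of per-plate estimates overstates true
  between-plate dispersion by the sampling noise of a k-well mean, so
  `sigma_inter = sqrt(max(0, s_between² − sigma_intra²/k))`; negative
  adjusted variances (expected occasionally at 3 plates) clamp to 0 with
  a warning.  For a single group, `s_between` is bias-corrected with
  `c4(n_plates)` before subtraction.  When several samples share a
  design, between-plate variances are pooled df-weighted across samples
  *before* the correction, which is applied once at the pooled degrees of
  freedom: correcting each 3-plate group separately would inflate the
  variance by `1/c4(3)² ≈ 1.27` and bias the pooled component upward by
  ~27%.
* **Copy-number specifics**: the between-pair component is estimated from
  each sample's per-pair mean log-ratio.  Reference-normalised relative
  copy numbers are computed (each replicate divided by the geometric mean
  of the reference sample's ratios on the same pair — geometric because
  the whole analysis is log-scale) and reported, but they are not used
  for the variance decomposition: a relative value carries the pair
  effects of both the sample and the reference, doubling the between-pair
  variance, whereas per-sample log-ratios isolate the single-sample
  component directly.
* **Precision relationships**: SD versus heteroplasmy uses ordinary least
  squares (Pearson r, two-sided p); SD versus Cq, which is monotone but
  not linear, uses Spearman rank correlation with average ranks.

## Replicate planning

A plate contributes one estimate per sample with SD
`sigma_plate = sqrt(sigma_inter² + sigma_intra²/k)`.  The number of
plates *n* per group for a two-sided pooled-variance two-sample t-test at
α = 0.05 to reach power 0.80 uses the exact noncentral-t distribution
(`df = 2n−2`, noncentrality `d/(sigma_plate·sqrt(2/n))`), scanning *n*
upward from the floor of 2 (one plate per group leaves no between-plate
degrees of freedom).  Power is strictly increasing in *n*, so the first
hit is minimal.  At extreme noncentrality, where scipy's noncentral-t CDF
loses precision, a normal approximation substitutes; by then power is
indistinguishable from 1.  Equal group sizes and the pooled-variance test
are assumed throughout — the designs compared are symmetric and share one
error model, so a Welch correction would only cost degrees of freedom.

Copy-number differences are fractional and act on the log scale:
"detect a 10% difference" means `d = ln(1.10)`.  This is the only mapping
consistent with reporting geometric SDs, and it reproduces the
high-concentration planning cells exactly.

### Rounding sensitivity of regenerated grids

The packaged reference grids were tabulated from unrounded variance
estimates; regenerating them from the 2-decimal published SD column
leaves almost every cell identical but moves a few: the 30%-deletion /
1%-difference cell (35 plates published, 34 from the rounded SD 1.45) and,
more broadly, the moderate/low-concentration copy-number cells, which are
sensitive to the 3-digit geometric SDs (up to 3 plates at low
concentration, 10% difference).  `reproduce-tables` reports these
discrepancies in its diff rather than suppressing them; the
high-concentration copy-number row and the deletion cells used in
validation regenerate exactly.  Likewise the 6-replicate SD column rebuilt
from the 3-replicate one matches to two decimals in 17 of 18 cells (the
60%-level cell lands at 0.7354 and re-rounds to 0.74 rather than the
published 0.73).

## Numerical and reproducibility choices

* Single root seed per run; per-plate RNG streams are spawned from it
  (`numpy` SeedSequence), so a plate's data are invariant to the total
  plate count.  Identical seed + design gives byte-identical tables.
* Validation errors name the offending field; analysis groups smaller
  than 4 values skip the outlier filter with a warning, plates with fewer
  than 2 wells are excluded from estimation with a warning.
* Display rounding (SDs and power to 2 decimals) happens only at the
  reporting boundary, never before computation.
* Test-suite problem sizes: the unbiasedness study uses 1e5 draws, the
  bootstrap coverage study 1,000 simulations × B = 1,000 resamples at
  n = 84, the end-to-end recovery study 500 seeds of the 6-sample,
  3-plate × 24-well design, and the power validation 1e4 trials per cell
  — sizes at which Monte-Carlo error is comfortably below the asserted
  tolerances.

## Known limitations

* Method-of-moments subtraction, not REML: with 3 plates the inter-plate
  SD estimate is noisy and clamps to zero in a noticeable fraction of
  runs; the pooled estimator exists precisely to mitigate this.
* The step-function Cq inflation is a coarse stand-in for a smooth
  error-versus-Cq curve; planning at low concentration should use the
  measured low-concentration SDs, not the simulator's inflation rule.
* No paired-design power analysis and no cost optimisation across the
  (plates, wells-per-plate) trade-off beyond the k ∈ {3, 6} grid.
* The ΔCq fallback (100% efficiency, slope −3.3219) when no standard
  curve is supplied biases quantities if true efficiencies differ between
  targets; it keeps ratios exact only when both targets share one
  efficiency.
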