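# Methods

## The inference problem

Given per-subject grey-matter (GM) probability maps on a common voxel grid,
an integer-labelled parcellation, and a two-group cohort (HC / ASC) pooled
from many acquisition sites, the package answers two questions per region:
how often does a mapping method declare the region different between groups
under repeated subsampling (probability of detection, PD, under the
HC-vs-ASC design; false-positive rate, FP, under the HC-vs-HC design), and
is the observed region statistic significant against a label-permutation
null? Two mapping arms are implemented — a region-level machine-learning
statistic corrected by a worst-case concentration bound, and a voxelwise
parametric t-map with cluster-level FWE — plus a calibrated region-mean
two-sample t-test that serves as the exact-level reference.

## Synthetic cohort model

The generator supplies the study material in place of real multi-site MRI.

- **Atlas.** An ellipsoidal brain mask (semi-axes 0.85 of the half-grid)
  partitioned by seeded Voronoi growth: `n_regions` in-mask voxels are drawn
  uniformly and every mask voxel takes its nearest site's label. Regions are
  contiguous and size-heterogeneous (coefficient of variation ≥ 0.3 for
  ≥ 20 regions; ~0.5 at the 116-region default), which the size-vs-power
  analyses need. Default grid 40×48×40 at 2 mm voxels (a desk-scale stand-in
  for the full 79×95×79 space, which remains available); default 116 regions.
- **Baseline GM.** A smooth radially decaying field from 0.8 at the mask
  centre to 0.2 at the boundary — GM probability stays inside [0, 1] after
  noise without frequent clipping. No claim of cortical realism is made.
- **Subject model.** value(v) = baseline(v) + site offset + group effect(v)
  + N(0, σ²), clipped to [0, 1], zero outside the mask. The group effect is
  a per-voxel standardized shift: ASC subjects get `d·σ` added inside the
  chosen effect regions. Defaults: σ = 0.05 (≈ the scale of between-subject
  GM variability relative to a 0–1 probability map), site offsets 0 unless
  configured, additive scalar per site when used. Noise is i.i.d. across
  voxels by default; an optional Gaussian-smoothed noise mode (config) adds
  spatial correlation but is not claimed to reproduce real GM covariance.
- **Corruption.** A fraction of subjects (default 0) get exactly
  `round(frac · |mask|)` voxels shifted by ±magnitude·σ (default 5% of
  voxels at 10 σ), emulating failed segmentation/registration. The cohort
  table records ground truth in a `corrupted` column.

What passing tests on this generator do show: calibration, error control,
rank recovery of planted effects, and the qualitative size-vs-power and
size-vs-FP relationships. What they do not show: behavior under realistic
spatial covariance, registration artifacts concentrated at region borders,
site-by-sequence interactions, or age/sex confounding.

## QC rule

Per voxel, z-scores are taken across the whole cohort (both groups pooled —
the only reference population that does not presuppose the group structure
under test), with the n−1 denominator and z = 0 wherever the voxel variance
is zero. A subject is *suspicious* when strictly more than 3% of in-mask
voxels have |z| > 5, and *excluded* when suspicious and confirmed; the
confirmation list (a stand-in for visual inspection) defaults to
confirm-all so pipelines stay automatable. A per-site variant is available.
Note the arithmetic constraint |z| ≤ (n−1)/√n: the |z| > 5 criterion can
only fire in cohorts of at least 27 subjects.

## Region-level agnostic arm

Per region, on the subjects × voxels matrix:

1. **Selection** — Welch two-sample t per voxel; keep the k = 50 largest
   |t| (all voxels if the region is smaller), ties broken by ascending
   index for determinism. Welch rather than pooled variance because
   unequal group variances are the norm in multi-site data.
2. **Extraction** — one PLS component (NIPALS): the weight vector is the
   unit-normalized centred cross-covariance Xᶜᵀy; scores are Xᶜw.
3. **Classification** — linear SVM, C = 1, on standardized scores;
   the statistic is the resubstitution ("replacement") accuracy.
4. **Worst-case correction** — `acc_wc = acc_emp − Δ(n, α)`, floored at 0,
   with n the total subjects in the comparison. Default bound:
   Vapnik-style `Δ = sqrt((h(ln(2n/h)+1) + ln(4/α))/n)`, h = 2 (oriented
   thresholds on one score). A plain Hoeffding deviation
   `sqrt(ln(2/α)/(2n))` is config-exposed.
5. **Decision** — one-sided z-test of `acc_wc` against chance:
   `z = (acc_wc − 0.5)/sqrt(0.25/n)`, significant iff z > Φ⁻¹(1−α);
   below-chance accuracy is never evidence of a difference.

**Why the complexity-bearing bound is the default.** Steps 1–3 are all fit
on the same sample, so the resubstitution accuracy is strongly optimistic:
under a pure null with i.i.d. voxels, selecting the top 50 of ~200 voxels
by |t| at n = 200 yields mean resubstitution accuracy ≈ 0.80. A bound with
no complexity term (Hoeffding, Δ ≈ 0.10 at n = 200) absorbs almost none of
that bias and the arm flags essentially every null region; the Vapnik-style
term (Δ ≈ 0.29 at n = 200) restores worst-case behavior — null flags
become rare, concentrate in the largest regions (where selection has the
most candidates), and vanish entirely for n ≲ 120, where Δ exceeds any
attainable accuracy excess. This residual large-n, large-region
anticonservatism is intrinsic to resubstitution-plus-bound inference and is
exactly why the permutation p-value layer, which re-runs the whole chain
under label shuffles, is the calibrated inference: label shuffles inflate
the null statistics by the same selection bias, so Eq.-1 p-values remain
valid regardless of the bound. The experiments reproduce this dissociation:
high raw detection frequencies in large regions under both designs, with
permutation p-values far from significance.

## Parametric arm

Volumes are smoothed with a separable Gaussian, σ_vox = FWHM/(voxel·2√(2 ln 2))
(8 mm default at 2 mm voxels → σ ≈ 1.699 voxels), renormalized inside the
brain mask (smooth(x·m)/smooth(m)) so boundary voxels are not attenuated
toward the zero background. The voxelwise statistic is the pooled-variance
two-sample t with df = n₁+n₂−2 (the design matrix of the two-group GLM
collapses to this special case); zero-variance voxels get t = 0 so
degenerate background cannot spawn clusters. Voxels above the one-sided
Student quantile for the cluster-forming p (default 0.001; 0.05 available
as the exploratory preset) form 26-connected clusters (6/18 configurable).
Cluster-level FWE uses a permutation max-cluster-size null: group labels
are permuted n_null times (default 199), the full t-map/threshold/label
pipeline is re-run, and each observed cluster gets
`p = (1 + #{null max ≥ size})/(n_null + 1)`, significant at p ≤ α. The
permutation null is exact under exchangeability, which the analytic
random-field alternative is not required for. Both ±1 contrasts are run and
each significant voxel is attributed to its (unique) atlas region.

## Resampling design

- **Outer loop** (R iterations, default 1000): draw a fresh subsample
  without replacement — n per group from HC and ASC pools (HC-vs-ASC), or
  two disjoint HC subsets (HC-vs-HC) — run the arm, record the per-region
  decision. PD/FP = flag count / R. Draw sizes: 100 per group for the
  all-centers design (~1/5 of each full group), floor(site pool/3) per
  group within a single site. Draws that cannot be satisfied (small sites)
  are counted as failures and reported, not raised: failed iterations are
  data about the design, not errors.
- **Inner loop** (M permutations, default 1000): on a label-faithful draw,
  the per-region statistic T (worst-case accuracy for the agnostic arm;
  largest suprathreshold cluster overlapping the region for the parametric
  arm; |t| for the calibrated arm) is compared against M label-shuffled
  re-runs: p = (#{T_π ≥ T} + 1)/(M + 1), ties counting toward the null.
  The two loops are deliberately separate: detection frequencies and
  permutation p-values answer different questions and are reported side by
  side. p-values are computed on `n_pvalue_draws` independent faithful
  draws (default 1); both the first draw's p and the across-draw mean are
  emitted.

All random streams derive from one seed (numpy Generator); identical
configurations reproduce results bit for bit.

## Numerical choices and degenerate inputs

- Welch t with zero denominator → t = 0; PLS on zero-variance features and
  single-class SVM inputs raise informative errors; k > region size falls
  back to the whole region.
- Permutation p-values live in [1/(M+1), 1] by construction and are
  super-uniform under the null.
- The permutation t-map engine computes all permuted maps with one
  indicator-matrix product (group sums and sums of squares), in float64,
  with a max(·, 0) guard against negative rounding of the pooled sum of
  squares.
- Region means use a reduceat over label-sorted voxel columns; region/label
  bookkeeping is validated (partition, unique ids/names) on atlas load.

## Problem sizes used in the shipped experiments

Tests and the acceptance script run at desk scale, chosen so the full suite
completes in minutes while keeping every statistical check meaningful:
40×48×40 grid (116 or 30 regions), cohorts of 40–300 subjects, R up to
1000 for the cheap calibrated arm, R of 20–50 for the classifier and
cluster arms, 199 permutations for FWE nulls, 200 null datasets for the
FWER estimate. The full-scale configuration (79×95×79, R = M = 1000,
20 sites) is expressible through the same interfaces.

## Known limitations

- The generator's i.i.d. noise understates spatial correlation; real GM
  maps would reduce the selection-overfitting gap between the two bound
  families and blur the cluster-size null.
- No covariate modeling (age/sex) in either arm; the subsampling is not
  stratified by covariates.
- The agnostic arm's raw flags are not calibrated at large n (see above);
  use the permutation p-values for inference.
- Cluster-level inference is one-sided per contrast; two-sided control is
  obtained by running both contrasts, without cross-contrast correction.
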