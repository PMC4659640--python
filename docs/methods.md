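# Methods

## Perimetry scoring

Each Humphrey 30-2 exam is a 76-point total-deviation grid per eye
(dB relative to age-matched norms; valid range -40 to +10). The grid is
idealised as the points (x, y) with |x|, |y| ∈ {3, 9, 15, 21, 27}
degrees inside the 30-degree circle, minus the outermost horizontal
point of each quadrant, giving exactly 19 points per quadrant and no
point on an axis. Eyes are averaged pointwise; a monocular exam is
accepted and passes through unchanged (robustness choice — homonymous
defects make the two eyes nearly redundant).

The visual field score (VFS) of a field is the **mean** total deviation
over its points; the hemifield VFS (38 points) therefore equals the
unweighted mean of the two quadrant VFS (19 points each). A summed
variant is retained behind `score="sum"` for sensitivity analyses, but
the mean is the default: baseline scores in the -20 to -30 dB range are
only interpretable as per-point means. The affected hemifield is the
side contralateral to the lesioned hemisphere and is supplied
explicitly in the covariate table rather than inferred from imaging.

Relative change is %VFS = (follow-up - baseline) / |baseline| x 100;
a zero baseline raises an error rather than returning infinity (real
baselines of defective fields are strictly negative). Improvement is
*significant* iff %VFS > 20 with a strict inequality; exactly 20 % is
*poor*. A field enters its outcome-specific analysis cohort when its
baseline VFS shows a defect, defined as mean total deviation ≤ -10 dB
(inclusive). The -10 dB default is this package's choice — the defect
criterion is a free parameter (`defect_threshold_db`) because no
standard value exists for quadrant-mean deviations; -10 dB sits well
below test-retest variability (~2 dB) yet above the floor of dense
defects.

## Regional extent of ischemic lesion

rEIL_r = 100 x (lesion voxels inside region r) / (region r voxels),
computed on the ipsilesional hemisphere's labels only (lesions are
unilateral PCA-territory infarcts; pooling hemispheres would halve
every value). Voxel-count ratios are used rather than mm³ since
numerator and denominator share the atlas grid. Lesion volume is a
native-space quantity: voxel count x dx·dy·dz / 1000 (mL), with the
z dimension including any inter-slice gap (a 5 mm slice with a 2 mm
gap contributes dz = 7 mm) so that slices tile the covered extent;
this is configurable through the mask's stored voxel dimensions.

Group lesion-frequency maps mirror right-hemisphere lesions onto the
left (axis-0 flip) by default, so maps read ipsilesional vs
contralesional rather than left vs right.

## Voxel-wise two-group test

Per voxel, lesion presence is Bernoulli within each improvement group;
groups are compared with the pooled two-proportion statistic
z = (p̂₁ - p̂₂) / sqrt(p̂(1-p̂)(1/n₁+1/n₂)), two-sided normal p-values,
and z = 0 where the pooled proportion is degenerate (0 or 1). The
normal reference is the appropriate large-m choice for thousands of
voxels; Fisher's exact test is available behind `method="fisher"` for
very small groups. Only voxels lesioned in at least one patient are
tested (untested voxels carry no information and would only dilute the
FDR denominator). Benjamini–Hochberg step-up selection controls FDR at
q = 0.05; the reported z threshold is the smallest |z| among selected
voxels. Testing is two-sided: the direction of interest is not fixed a
priori, although excess lesion frequency in poor recoverers is the
expected pattern.

## Classification protocol

* **Random chance** is the majority-class fraction of the full cohort
  (not of a test fold): the accuracy of always guessing the larger
  group.
* **Splits.** Per class, round-half-up(0.7 x n) patients train and the
  rest test, clamped so both folds keep at least one member of each
  class; sampling is uniform without replacement from a seeded
  generator. 100 repeats by default.
* **Learner.** Linear-kernel soft-margin SVM with C = 1; features are
  z-scored with training-fold mean/SD. Training-fold zero-variance
  features are dropped with a warning; if none survive, the classifier
  degenerates to predicting the training-fold majority class. C = 1
  and autoscaling mirror the common toolbox defaults for this
  protocol; nothing beyond the linear kernel is specified by the
  design. The inner loop calls scikit-learn's low-level libsvm binding
  directly (identical solver to `SVC`, verified prediction-identical in
  the test suite) because the exhaustive search performs ~10⁵ fits.
* **Subset search.** All 2^M - 1 non-empty column subsets are evaluated
  on the *same* sequence of splits (common random numbers), so subset
  accuracy vectors are pairable and differences between subsets are not
  confounded by split luck. A guard rejects M > 20. The best subset
  maximises the one-sample t-score of its accuracy distribution against
  random chance; ties break toward smaller subsets, then lexicographic
  column order, making reports deterministic. Runs with zero accuracy
  SD get t = +∞ (p = 0) as a sentinel rather than NaN, so perfectly
  stable runs rank above all finite ones. At small repeat counts this
  sentinel can promote constant-accuracy subsets with mediocre means;
  at the protocol's 100 repeats such degeneracies are rare.
* **Paired comparisons.** Two runs sharing a split digest are compared
  with a paired t-test over per-split accuracy differences; a spread
  below 1e-12 (a constant shift up to rounding) maps to the ±∞/0/1
  sentinels. Bonferroni correction multiplies by the number of
  comparisons actually reported in a family.

## Group statistics

Continuous variables: two-sample Student's t-test with pooled variance
(Welch behind a flag). Binary variables: Pearson chi-square without
continuity correction, switching to Fisher's exact test when any
expected cell count is below 5. Associations with %VFS use Pearson
product-moment correlation with binary predictors coded 0/1
(point-biserial). `pooled_mean` reconstructs whole-cohort means from
per-group means and sizes (Σnᵢmᵢ/Σnᵢ).

Note that the random-chance formula applied to the improvement-group
sizes gives 57.1 % (hemifield), 59.4 % (upper) and 55.2 % (lower) for
a 20/15, 13/19, 13/16 cohort; published figures computed on the same
design have differed slightly for the quadrant outcomes, and this
package always reports the formula value.

## Synthetic study generator

The generator emulates the statistical structure the analysis assumes,
under a single cohort seed that derives all sub-generators:

* **Atlas.** Nine contiguous blocks per hemisphere on a 32³ grid
  (2 mm voxels), hemisphere split on the first axis, with unlabelled
  margins standing in for white matter and unlisted cortex.
* **Lesions.** A per-patient severity factor s ~ Beta(4,4) scales
  region-specific base fractions (derived from published cohort-level
  mean involvements: lingual 0.48 down to middle occipital 0.085),
  each multiplied by an independent lognormal(0, 0.8) factor; voxels
  are accreted distance-first from a random seed voxel until the
  target fraction is met (achieved rEIL within ±2 points of target).
  An additional Beta(1.2, 2.5) fraction of the hemisphere's unlabelled
  voxels joins the lesion: it adds volume but no rEIL, which is what
  makes total volume a much weaker predictor than regional extent —
  matching the observed dissociation. Native-space volume uses
  0.651 x 0.651 x 7 mm voxels (5 mm slice + 2 mm gap).
* **Covariates.** Prevalences near the study cohort (80 % male, 51 %
  left PCA, 69 % hypertension, ...), age ~ N(61.6, 11), onset-to-MR
  time ~ Gamma(1.4, 26.6) h (right-skewed, mean ≈ 37 h).
* **Outcome model.** Quadrant %VFS = 47 - 0.55·rEIL_calcarine -
  0.30·rEIL_lingual - 0.25·rEIL_cuneus + 15·[left PCA] -
  0.20·MR-time(h) + N(0, 18), independently per quadrant, clipped only
  where the follow-up mean would leave the measurable dB range.
  Baseline quadrant VFS is -(8 + 0.25·(calcarine + lingual-or-cuneus))
  + N(0, 8) dB, clipped to [-38, -3]; the 8 dB noise keeps the
  baseline-outcome correlation near its observed ~0.5. Coefficient
  signs are the planted ground truth (regional involvement and longer
  onset-to-imaging delay worsen recovery; left-sided lesions recover
  better); magnitudes were chosen so cohort-level correlations match
  the observed ones (calcarine ≈ -0.55, volume ≈ -0.2).
* **Exams.** Point values are the quadrant mean plus zero-sum jitter
  (rescaled after centering so no point leaves [-40, +10] dB), with a
  symmetric inter-eye perturbation; quadrant means — and hence %VFS —
  are reproduced through the scoring pipeline to ~1e-9.

What the generator does **not** model: realistic vascular-territory
lesion geometry, imaging noise or registration error, ceiling effects
in mild defects, direct causal influence of baseline severity on
recovery (their correlation here is entirely lesion-mediated), or
measurement dependence between eyes. Passing recovery tests therefore
demonstrates that the pipeline detects the planted structure at
realistic sample sizes and noise levels — not that real data contain
that structure.

The generator's linear-Gaussian outcome model matched to marginal
correlation magnitudes cannot simultaneously reproduce every published
multivariate contrast; in particular the gain from adding regional
extents to an already-strong baseline predictor set is smaller here
than reported on the real cohort, so the corresponding test asserts
the guaranteed monotonicity of the search plus majority-rate strict
improvement.

## Numerical choices and problem sizes

* Strict inequalities at classification boundaries (>20 %); the defect
  cut is inclusive (≤ -10 dB).
* BH selection delegates to `statsmodels.stats.multitest`; tests pin it
  against an independently coded step-up oracle.
* Paired-t and t-score degeneracies use ±∞/0/1 sentinels as above.
* The acceptance script runs the classification recovery at the full
  100-split protocol over 50 replicate cohorts of n = 35, the
  correlation recovery over 50 cohorts of n = 100, and the voxel-test
  null calibration with 200 voxels x 500 replicates; these sizes give
  Monte-Carlo error comfortably below the asserted margins.

## Known limitations

* Registration to atlas space is a documented precondition, not a
  pipeline stage; masks must arrive in atlas space.
* The exact-statistic option (Fisher) for the voxel test is O(voxels)
  in Python and intended for small grids.
* Proprietary perimetry exports are not parsed; exams arrive as CSV.
* Reliability exclusions (fixation losses, false responses) are an
  upstream decision recorded as data, not re-derived.
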