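# Methods

## The measurement

Background parenchymal enhancement (BPE) is the contrast uptake of normal
fibroglandular tissue (FGT) on dynamic contrast-enhanced breast MRI. Given a
pre-contrast fat-suppressed T1 volume `I_pre` and one early post-contrast
volume `I_post` resampled onto the pre-contrast grid, the package computes,
per voxel,

    R_voxel = (I_post − I_pre) / I_pre

and summarises a study by

    FGT%   = V_FGT / V_Breast × 100
    V_BPE  = Σ_{voxel ∈ FGT} V_voxel  such that  R_voxel ≥ 0.20
    BPE20% = V_BPE / V_FGT × 100
    ΔBPE20% = (BPE20%_post − BPE20%_pre) / BPE20%_pre × 100

with physical voxel volumes (product of the spacings, mm³). The threshold
comparison is inclusive (≥) and the threshold is configurable with default
0.20. `ΔBPE20%` is undefined when the baseline is zero and reported as an
explicit error.

Processing order per study: N4 bias-field correction of each volume →
registration of the post volume onto the pre-contrast grid → supervised
chest-wall delimitation intersected with an air/body intensity threshold →
two-class fuzzy C-means FGT segmentation inside the breast mask → ratio map →
metrics. All masks live on the pre-contrast grid and are never interpolated.

## Which intensities feed the ratio

The ratio map is computed from the **raw** (uncorrected) intensities, with
the registration transform estimated on the bias-corrected pair and then
applied to the raw post volume. The coil sensitivity field is common to the
pre and post acquisitions of one session and is multiplicative, so it cancels
exactly in `(I_post − I_pre)/I_pre`. Dividing by two *independently
estimated* fields instead injects their differential error into the ratio;
on phantoms this distortion reaches ~10% of the ratio scale, because the
field estimated from the post volume partially absorbs genuine enhancement
blobs. Bias correction therefore serves segmentation and registration, not
the ratio. `RunConfig.ratio_on_corrected = True` restores the
corrected-intensity alternative.

Voxels with `I_pre` at or below a floor — default 1% of the median
pre-contrast intensity inside the breast mask — are marked invalid (the
ratio explodes on near-zero fat-suppressed voxels), counted in `n_invalid`,
and excluded from both the numerator and the denominator of BPE20%. The
full-FGT denominator is available via `valid_denominator=False`.

## Stage notes

**Bias correction** delegates to the N4 algorithm (SimpleITK), run per
volume on a body mask, with the fitted log-field resampled to full
resolution and normalised to mean 1 over the mask so that correction
preserves mean in-mask intensity. Defaults: 4 fitting levels × 50
iterations, 4 B-spline control points per axis, shrink factor 2. The body
mask is the lowest cut of a three-class Otsu split (air | fat | glandular);
a two-class Otsu split is unreliable here because on post-contrast or
FGT-rich volumes it separates fat from glandular tissue rather than air from
body.

**Registration** minimises mean squared difference over a multi-resolution
pyramid (shrink 4/2/1). The default transform is pure translation;
`reg.mode` upgrades to rigid (translation + rotation) or to a
demons-deformable refinement. Translation is the default because pre/early
post acquisitions minutes apart in the same position show drift-like motion,
and on desk-scale data the extra rotational degrees of freedom fit spurious
sub-degree rotations whose only effect is to force fractional-voxel
resampling everywhere — which erodes thresholded voxel counts at tissue
boundaries without improving alignment. Non-convergence (final similarity
above the initial one) raises rather than returning a bad alignment.

**Chest-wall delimitation** is supervised, as either an explicit posterior
exclusion mask or operator control points on the wall surface fitted by
least-squares polynomial interpolation `y = f(x, z)` (degree 1 by default;
the fitted surface partitions the grid with no gaps). The breast mask is the
anterior region intersected with the air/body threshold; connected
components and holes below 27 voxels are removed (clipped air noise
otherwise passes the threshold as isolated specks and inflates `V_Breast` by
several percent at the highest simulated noise). An optional tumor mask is
subtracted, mirroring analysis of the non-tumor breast.

**FGT segmentation** is two-class fuzzy C-means on the in-mask
bias-corrected intensities, written in-house (it is the core of the
segmentation step): memberships `u_ij ∝ (1/d_ij²)^(1/(m−1))` row-normalised,
centres as `u^m`-weighted means, fuzzifier `m = 2`, convergence when the
largest centre movement falls below `1e-5` of the data range (this relative
tolerance is what makes the segmentation exactly invariant to global
intensity scaling), 300-iteration cap, deterministic quantile
initialisation. A voxel lying exactly on a centre receives membership 1 for
that cluster. The FGT class is selected by polarity — brighter by default,
correct for fat-suppressed T1; `fgt_brighter=False` flips it for
non-fat-suppressed protocols — and binarised at membership 0.5. A
homogeneous breast (class centres closer than `1e-3` of the intensity
spread) is reported as degenerate rather than split arbitrarily.

## The phantom

The synthetic generator provides ground truth for every stage: two
half-ellipsoid breasts against a planar chest wall on a 64³ grid (default
spacing 1 × 1 × 1.5 mm), an FGT compartment grown as spatially correlated
blobs (smoothed-noise scoring plus a depth prior, quantile-selected so the
target FGT fraction is hit to the voxel), and an enhancing sub-compartment
selected the same way inside FGT. Non-enhancing FGT enhances at
`ratio_low = 0.05`, enhancing FGT at `ratio_high = 0.5` — plausible levels
for the early post-contrast phase, where tissue flagged as enhancing
typically rises 30–100% and the remainder only a few percent. The post
volume is `pre × (1 + R)` voxel-wise; a smooth multiplicative field with
peak deviation `bias_amplitude` (shared by pre and post, matching the
multiplicative model N4 assumes) is applied to both; a rigid translation is
applied to the post volume only; Gaussian noise (scale relative to the mean
FGT intensity) is added last and intensities are clipped at zero. Default
tissue levels are FGT 500, fat 150, background 0 (fat-suppressed polarity;
configurable). Everything is driven by one integer seed and regenerating
with the same parameters is byte-identical.

What the phantom does **not** emulate: pharmacokinetic time curves (a single
early phase only), Rician noise (Gaussian is used; at the simulated SNRs the
distinction is immaterial to threshold-count metrics), partial-volume
fractions at tissue interfaces (labels are crisp), coil-array geometry, and
lesions (an optional enhancing sphere is out of scope). Recovery results on
the phantom therefore show that the pipeline inverts its own generative
model under noise, bias and motion — not that it reproduces clinical
variability.

## Validation sweep and its design choices

End-to-end recovery is assessed on 20 phantoms: the full factorial of FGT
fraction {0.05, 0.1, 0.2} × enhancing fraction {0, 0.2, 0.5, 0.8} cycled to
20 cases, with noise drawn uniformly in [0, 0.05], bias amplitude in
[0, 0.3], and rigid motion up to 2 mm per axis in whole millimetres on a
1 mm isotropic grid. The pass condition is BPE20% and FGT% within 2
percentage points of truth in at least 90% of cases.

Motion in the sweep is grid-commensurate by design. The phantom's
enhancement field is piecewise constant, so a single linear-interpolation
resampling at a fractional-voxel offset blends enhancing FGT with darker fat
across blob boundaries and can depress the thresholded count by 10–15
points at high enhancing fractions — a property of any resampling scheme
applied to crisp labels, not of the registration or the metric. Whole-voxel
motion isolates what the sweep is meant to test (registration, bias and
segmentation recovery); translation recovery at fractional offsets is
verified separately at the stage level (within 0.5 voxel per axis), and the
partial-volume sensitivity is acknowledged here as a limitation of
validating threshold-count metrics on crisp phantoms.

Problem sizes used throughout the test battery and the acceptance script:
64³ grids for phantoms; 1,000 random grids up to 16³ for the exact
brute-force comparison of the metric core; n = 500 for Cox parameter
recovery and 30 replicate cohorts of n = 100 (~15 events each) for the
association-detection rate.

## Statistics layer

Sensitivity and specificity come with 95% Wald intervals
`p ± 1.96√(p(1−p)/n)` clipped to [0, 100]; exact Clopper–Pearson intervals
are available by option. Rater agreement is Cohen's kappa for two raters
(with the large-sample null-variance z test) and Fleiss' kappa for three or
more; the two differ for two raters (pooled versus per-rater marginals), so
both are exposed. Pearson correlation and the Student t test (pooled
variance; Welch by option) wrap scipy. Recurrence-free survival uses a
multivariate Cox proportional-hazards wrapper around lifelines, excluding
patients lost to follow-up, with listwise deletion per analysis; it reports
each covariate on both scales (log-hazard coefficient and hazard ratio) with
95% CIs, per-covariate Wald p-values, and the model-level likelihood-ratio
p-value. Zero events and non-convergence (e.g. complete separation) are
explicit errors. No multiple-testing correction is applied; the working
significance level is 0.05.

The cohort simulator draws post-treatment BPE20% per patient and generates
exponential recurrence times whose hazard scales as
`exp(β · z(bpe20_post))`, censored administratively; defaults give roughly
15 events per 100 patients, so detection-rate simulations are structural
analogues of a small-cohort survival analysis, not reproductions of any
clinical estimate.

## Degenerate inputs and numerical conventions

Grids must be ≥ 8 voxels per axis; an empty FGT mask, an empty anterior
region, an all-censored cohort, constant raters, and a zero BPE20% baseline
for ΔBPE20% are all explicit errors rather than NaNs. Percentages carry
full precision internally; rounding (to integer percent for diagnostic
accuracy, 0.1 for metric displays) happens only at the report/CLI layer.
Ties at the membership cutoff (0.5) and at the enhancement threshold are
included, both comparisons being ≥.
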