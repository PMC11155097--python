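# Methods

This note documents the models, conventions and numerical choices behind
`mipradiomics`, and what the synthetic validation does and does not show.

## Imaging conventions

Volumes are `(slice, row, col)` with 0-based indexing; the axial MIP reduces
axis 0. Subtraction is voxelwise post − pre with negatives clamped to 0 (the
standard subtraction-display convention; enhancement is non-negative by
definition). Only the first post-contrast phase is consumed: it offers the
greatest lesion conspicuity, the lowest background parenchymal enhancement
(BPE), and the best angiographic effect. Intensities stay in native
arbitrary units through I/O and segmentation; normalization happens once, at
feature scaling. Negative spacing signs in NIfTI affines are normalized to
absolute values with a warning.

## Vessel segmentation

**Breast mask.** Median smoothing (5×5), Otsu threshold, morphological
closing (disc radius 5), hole filling, largest connected component. The
degenerate all-foreground case falls back to the full frame minus a 1-px
border, with a warning.

**Lateral mask.** The breast restricted to the image half (split at the
vertical midline column W/2) containing the tumor centroid; a centroid
exactly on the midline goes left, with a warning.

**Vesselness.** 2D Frangi-type eigenvalue filter. Per scale σ ∈ {1…6} px:
Gaussian second derivatives scaled by σ² (γ = 2 normalization, which
equalizes the response of tubes across scales), eigenvalues ordered
|λ₁| ≤ |λ₂|, response zero where λ₂ > 0 (dark ridges), otherwise
exp(−R_B²/2β²)(1 − exp(−S²/2c²)) with R_B = λ₁/λ₂ and S the Frobenius norm
of the Hessian. β = 0.5; c defaults to half the per-scale maximum of S
(image-adaptive, so the structureness term spans (0, 1) regardless of
intensity units); both are configurable. The final map is the pixelwise
maximum over scales, with the argmax scale recorded. The image is centered
(mean subtracted) before filtering because sampled Gaussian-derivative
kernels do not sum exactly to zero, which would otherwise leak a constant
offset into the Hessian and break offset invariance.

**Binarization and cleaning.** Threshold (Otsu over the nonzero response
inside the lateral mask, or a fixed configured value), closing with a disc
of radius 1 to reduce small gaps, *small*-hole filling, removal of
components smaller than 20 px, and intersection with the lateral mask. Hole
filling is capped at 64 px (configurable): unrestricted filling floods the
interior of any bright blob whose rim is detected as a closed curvilinear
ring — in practice the tumor — into the vessel mask. The cap preserves the
intent (closing the small holes left inside tubes) without that artifact.

**Tumor/vessel disjointness.** Contested pixels are assigned to the vessel
mask and erased from the tumor ROI; emptying the tumor entirely is a
contract error. In the pipeline the vessel *search region* additionally
excludes the 2-px-eroded tumor interior: the tumor is already delineated and
its interior is not vasculature, so only the rim stays contestable. This is
the automated stand-in for the manual erase-incorrect-voxels editing step of
the clinical workflow.

**Detection metrics.** Both masks are skeletonized; skeletons are split into
segments at branch points (pixels with more than two 8-neighbors). A
reference segment is *correct* if at least 50% of its pixels lie within 2 px
of the prediction, else *missed*; a predicted segment with less than 50%
reference support is *incorrect*. Correct and missed rates are normalized by
the reference segment count (hence complementary); the incorrect rate is
normalized by the predicted segment count, which is why it is not the
complement of the correct rate. Segment-level (rather than pixel-level)
scoring matches how discrete vessel detections are counted in practice, and
the radius/coverage constants are configurable. An empty prediction scores
0 / 0 / 100 by convention.

## Radiomics features

Gray levels use a fixed bin width (default 25 native intensity units)
anchored at the in-mask minimum: level = ⌊(x − min)/w⌋ + 1. Anchoring at the
minimum makes every texture feature invariant to constant intensity shifts.

Feature bank (standard reference-set definitions): 10 shape-2D, 19
first-order (including standard deviation; skewness and kurtosis of a
constant ROI are defined as 0, and kurtosis is the raw fourth standardized
moment), and 70 texture features — GLCM 24 (symmetric, distance 1, feature
values averaged over the four planar angles), GLRLM 16 (four directions,
averaged), GLSZM 16 (8-connected zones), GLDM 14. The 24+16+16+14
decomposition is the unique standard-family combination totalling 70, and
455 = 10 + 5×(19+70) then follows exactly for tumor ROIs (original channel
plus four wavelet sub-bands; shape is computed once, on the original mask).
Vessel ROIs use the original channel only: 99 features.

**GLDM convention.** The dependence of a pixel is its count of in-mask
neighbors within Chebyshev distance δ = 1 whose level differs by at most
α = 0 — a 0-based convention under which the center pixel of a uniform 3×3
ROI has dependence 8 and LargeDependenceEmphasis = (4·3² + 4·5² + 8²)/9 =
200/9. Reference toolkits differ here (some count the center pixel, making
the minimum dependence 1); the 1-based alternative is available via
`dependence_base=1`. Inverse-dependence emphases use divisor max(d, 1) so
the 0-based convention stays finite for isolated pixels.

**Shape.** Mesh surface integrates the signed shoelace areas of the
0.5-isocontours (holes wind oppositely and subtract). The perimeter uses the
Crofton formula with 4 directions, which is asymptotically unbiased for
smooth boundaries where marching-squares polygon lengths overestimate by
5–8% (a digital disc of radius 20 then scores sphericity ≈ 0.98 instead of
0.93); Crofton assumes isotropic sampling, so anisotropic spacing enters as
the mean pitch. Axis lengths are 4√λ of the coordinate covariance
eigenvalues; elongation is √(λ_minor/λ_major).

**Wavelets.** Single-level undecimated (stationary) transform with coiflet-1,
`norm=True`; odd dimensions are reflect-padded to even and cropped back, so
all four sub-bands keep the raster size and the ROI mask applies unchanged.
Decimated sub-bands would halve the raster and invalidate the mask, which is
why the undecimated form is used.

## Modeling

Min–max scaling to [0, 1] is learned from training rows only; validation
values are clipped to [0, 1] and constant training features map to 0.

Feature selection is recursive feature elimination with a LASSO estimator:
the penalty α is chosen once by 5-fold cross-validation (shuffled folds,
seeded) on the full scaled training matrix, then held fixed while the
feature with the smallest absolute coefficient is dropped (step 1) until
`n_target` (default 10) remain. Re-tuning α at every one of ~450 elimination
steps would multiply cost for no stability gain; the single CV fit is the
deliberate choice. If the LASSO zeroes every coefficient at some step —
routine under a null effect — the feature with the weakest univariate
(point-biserial) association is dropped instead, with a single warning.
`n_target` is an analysis parameter, not a constant of the method: selected
set sizes observed on real data are outcomes, not inputs.

The k-NN scorer (k = 5, Euclidean distance, uniform weights) assigns the
positive fraction among the k nearest training rows, so scores are
quantized to {0, 0.2, …, 1}. Exact distance ties are broken by training-row
order via a stable argsort, making predictions fully deterministic.

Score fusion: elementwise minimum, maximum, or w·tumor + (1−w)·vessel for
w ∈ {0.1 … 0.9}; the grid's best rule is selected by training-cohort AUC and
carried to validation.

## Evaluation

AUC is the mid-rank Mann–Whitney statistic (ties get half credit), which the
tests verify against exhaustive pair counting. Variances, 95% CIs and the
paired two-sided z-test use the DeLong structural-component estimator;
intervals use the normal approximation truncated to [0, 1], and a zero
variance with AUC ∈ {0, 1} collapses the CI to a point with a warning.
Identical paired scores give p = 1 by convention. Classification metrics
(accuracy, precision, recall/sensitivity, specificity) use a threshold
chosen by the Youden index on a designated training score set (largest
maximizer on ties) and carried, not re-fit, to validation sets. Report
tables round AUC to 2 decimals and rates to 1 decimal. No multiple-testing
correction is applied; p-values are reported raw.

## Synthetic phantoms

Each phantom is a 256×256 image (arbitrary intensity units) containing a
half-elliptical breast (mean 60, plus smoothed noise of amplitude 8 and
correlation length 8 px emulating minimal BPE), one irregular tumor blob
(ellipse perturbed by smoothed noise; mean 170 with smooth internal texture
of amplitude 18, correlation length 2 px), and 1–8 vessels built from
quadratic Bézier trunks with 1–3 branches, widths drawn uniformly from
1–4 px, mean intensity 185 with an across-vessel spread of SD 12 and a
small along-vessel modulation; white noise of SD 4 overlays everything.
Defaults: 5 vessels, tumor radius 10–18 px, cohort prevalence 0.355 with
exactly round(n·prevalence) positive labels (deterministic by design, not
binomially sampled), per-case seeds derived from the cohort seed.

The class effect multiplies the across-vessel intensity SD and the tumor
texture amplitude by (1 + effect) for label-0 cases (the non-pCR analogue,
whose angiogenic vasculature is the more heterogeneous). All random draws
occur in a fixed order regardless of the label, so effect = 0 makes the two
classes identical in law and the same seed yields bit-identical images. The
effect deliberately lands in the feature families the analysis selects on
real data — vessel gray-level-dependence heterogeneity and tumor wavelet-LL
texture — so end-to-end recovery exercises the selected-feature pathway.
Effect sizes used in validation: 0.5 (moderate illustration), 2.0 (large,
for recovery tests).

**What passing tests show — and do not.** The synthetic experiments
demonstrate that the implementation is internally correct: the filter finds
the curvilinear structures it is designed for, the features respond to the
injected heterogeneity, selection finds the informative features among 455,
fusion behaves as an average should, and the null pipeline is calibrated
(validation AUC near 0.5, DeLong type-I error near 5%). They do not
establish clinical performance: the phantoms lack real anatomy, marked BPE,
motion or coil artifacts, scanner variation, and the label-feature link is
injected rather than biological.

## Problem sizes

The recovery and null experiments use cohorts of 120 training + 120
validation phantoms (prevalence 0.355) — comparable to the clinical cohort
sizes this analysis targets — and the DeLong calibration uses 1000 null
replicates of n = 60. The class-effect monotonicity check uses 50 phantoms
per class per effect level.

## Known limitations

Single-MIP 2D analysis only; no 3D segmentation, registration, kinetic
modeling, or contralateral-breast comparison. The exact constants of the
reference multiscale filter and the supplementary post-processing order are
not public; the implemented formulation and all constants (scales, β, c,
threshold, minimum component size, hole cap, match radius) are exposed in
configuration and documented above. Whether clinical CIs of this kind are
DeLong- or bootstrap-based varies by report; output here is labeled DeLong.
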