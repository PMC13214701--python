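# Methods

This note records the models, numerical choices and open design
decisions behind `octseg`, and what the synthetic tests do and do not
establish about real data.

## Attenuation estimator

The depth-resolved attenuation coefficient divides each pixel's linear
intensity by twice the axial pitch times the truncated tail sum of its
A-scan. The estimator is exact for a signal that has fully decayed by
the bottom of the scan; for a finite scan it carries a multiplicative
bias `1/(1 − r^(N−j))` with `r = exp(−2μΔ)`, i.e. of order
`exp(−2μΔ(N−j))` relative, growing toward the bottom. We deliberately
add no tail-correction term: the bias is characterized in tests (the
truncated geometric-series closed form is the oracle) rather than
corrected, keeping the estimator exactly the simple ratio. Two further
consequences are tested as invariants: the estimate is invariant under
any global rescaling of an A-scan (the intensity cancels), and for a
noiseless exponential at small `μΔ` the asymptotic value
`(1 − e^(−2μΔ))/(2Δ)` sits within `2μ²Δ` of the true `μ`
(second-order expansion bound; at Δ = 7.5 μm and μ = 1 mm⁻¹ the
systematic shortfall is 0.75%).

Columns are summed bottom-up so the small deep values accumulate before
the large shallow ones. All computation is double precision. A zero
tail sum yields NaN, the package-wide sentinel for undefined/masked
cells — sentinels propagate and are never compared or imputed.

## Speckle contrast

The refined speckle contrast is the windowed dispersion of the
attenuation field divided by its windowed mean, over a centred
10 × 20 px window. Standard deviation over mean (the conventional
speckle-contrast normalisation, which is dimensionless and
scale-invariant) is the default; variance over mean is available as
`mode="variance"` since the dispersion convention differs between
formulations and both are defensible. Windows are centred with no
border padding invented: output within half a window of the border is
masked. Masked (sub-noise-floor or undefined) cells are excluded from
the window statistics entirely; a window needs at least 2 contributing
cells and a positive mean, and the output cell must itself be valid.
An alternative, masking any window that touches an invalid cell, would
discard most of the map around the noise-floor transition; excluding
the cells instead keeps the estimate local and is verified against a
delete-the-cells oracle.

## SNR masking

The 15 dB cutoff needs a noise reference, which the hardware does not
hand us; when the sidecar does not supply one it is estimated as the
median intensity of the bottom 5% of rows, the region of a
deep-enough scan where tissue signal has decayed into the noise bed.
The mask is applied to the parametric maps and excludes pixels from
speckle windows and feature means; the structural intensities
themselves are left untouched.

## Features and blocks

Blocks are 20 adjacent A-scans; features are the mean OAC and mean RSC
over depth rows [20, 40) (half-open, 20 rows — the "rows 20–40" ROI is
resolved half-open for consistency with every other interval in the
package, and is configurable). Widths not divisible by the block size
drop the remainder columns rather than padding, keeping block
statistics identically distributed. Means are over valid cells only; a
block whose ROI is less than 50% valid (configurable) is flagged
invalid, reported, and excluded from training and classification —
never imputed.

## Classifier

A linear-kernel SVM per class against the rest (explicit one-vs-rest,
libsvm hinge loss, C = 1.0 by default — the regularisation strength is
exposed because nothing in the problem pins it), on features
standardised to zero mean and unit variance. The trained model is a
JSON manifest of scaler statistics, weights and intercepts; prediction
is an explicit argmax of the per-class decision values with exact ties
broken by the fixed order Normal < DamagedMatter < Tumor, so results
are reproducible from the manifest alone without a pickled estimator.
Non-linear kernels are out of scope: at tens of training scans they
would overfit, and the linear boundary is the interpretable object the
downstream review step relies on.

Cross-validation is leave-one-group-out with the scaler and SVM refit
inside every fold. The default grouping is per scan: blocks within a
scan share speckle and texture realisations, so per-block folds leak
information; per-block grouping remains available where the literal
block-level protocol is wanted. A fold whose training remainder loses a
class is a hard error rather than a silently degenerate fit. The binary
tumor-vs-rest score is the Tumor class's raw decision value — no
probability calibration, which would add a fitted layer without
changing the ranking. ROC/AUC uses the threshold sweep over unique
score values (trapezoidal area), which equals the concordant-pair
statistic with half-credit ties; tests enforce that identity against an
exhaustive pair-counting oracle.

## Contextual filter

The filter is a deterministic model of the human contextual review of a
segmentation map — not a claim about surgeon cognition. The qualitative
rules (scattered red amid green is noise; dense red, red adjoining
yellow, and deep-reaching red are credible) are quantified by
engineering defaults, all configurable: minimum credible run length 2,
density thresholds 0.10/0.30 of blocks, yellow-neighbour amplification
×1.5, minimum depth fraction 0.5, decision threshold 0.5 (strict).

Composition: the surviving red fraction maps to a base score (0.1
below the low threshold, 0.9 above the high one, linear between), and
amplification/attenuation act on the evidence above the no-evidence
baseline, `p = clip(0.1 + (base − 0.1)·amp·depth_factor)`. A bare
product of factors would let shallow weak evidence score *below* the
no-evidence baseline, violating the monotonicity requirement that
adding a red block never lowers the probability; anchoring at the
baseline preserves it, and the property is hypothesis-tested. Depth
evidence per block comes from the SNR-mask depth extent (the
structural signal support), taking the maximum over surviving red
blocks — a maximum, unlike a mean, cannot decrease when evidence is
added. A run touching the scan edge is judged on its single existing
neighbour.

## Reader-study statistics

Confusion counts pool all (scan, reader) assessments. Sensitivity,
specificity and accuracy are reported as proportions and as half-up
whole-percent roundings for display; a zero-denominator metric is
undefined (None), never zero. Consistency defaults to mean pairwise
percent agreement — the most direct reading of "degree of agreement
among readers" — with Fleiss' κ (via statsmodels) as the
chance-corrected alternative; with unpublished per-scan rater data the
two are not interchangeable and neither is claimed to reproduce any
particular published consistency value.

The bootstrap resamples scans with replacement (each resampled scan
keeps its full reader-call vector and truth; the scan count per
iteration equals the original), 10,000 iterations, CI = empirical
2.5/97.5 percentiles, fully determined by the seed. An assessment-pair
resampling mode is provided for single-output-per-scan settings where
pairs are the natural unit. Iterations where the statistic is
undefined (a resample without positives, say) are dropped; more than
50% undefined aborts with a diagnostic rather than returning a
meaningless interval. Modality comparison reports CI overlap
mechanically and adds no hypothesis tests.

## Synthetic generator

Each pixel's mean intensity is `I0 · T · exp(−2 μs Δ j)`; the realised
intensity multiplies a unit-mean exponential speckle deviate (fully
developed speckle, CV = 1) and adds an exponential noise floor.
`T` is a unit-mean lognormal reflectivity texture field, white in depth
and laterally smoothed at a 3-column correlation length. The texture
must vary along depth to be observable at all: a per-column constant
cancels exactly in the attenuation ratio. Class defaults —
μs = 1.0 / 2.0 / 3.5 mm⁻¹ and texture σ = 0.10 / 0.30 / 0.55 for
normal / damaged / tumor — are generator constants chosen once to make
the classes separable but overlapping in (OAC, RSC) space; they are not
measured tissue values. Geometry defaults to 256 depth pixels at
7.5 μm pitch and a configurable width (512 for full scans, 400 for
training-style scans). Defaults put the surface around 40 dB above the
noise floor, so normal white matter stays above the 15 dB cutoff over
the full depth while tumor columns fall below it near 110 px — which is
also what feeds the filter's depth-evidence rule.

Deliberately not modelled: axial point-spread convolution, confocal and
sensitivity roll-off, polarization channels, refraction at the tissue
surface, and multiple scattering. Consequently the simulator validates
the *logic* of the pipeline (estimator identities, masking semantics,
fold containment, rule behaviour, statistical calibration), not its
diagnostic performance on tissue: passing tests say nothing about
real-world AUC, and the near-perfect separability of homogeneous
synthetic scans is a property of the phantom, not a performance claim.

The archetype segmentation-map cohort (9 scattered false-positive
scans, 4 clustered, plus optional true-infiltration and clean scans)
encodes the two spatial failure families directly at block level;
scattered singletons are suppressible by construction while clustered
runs are morphologically tumor-like, which is exactly the distinction
the filter is designed to make — so the 9-of-13 override outcome is a
consistency check of the rule engine against its specification, not an
empirical discovery.

## Problem sizes

The test suite and acceptance script run on deliberately small
instances: 23 training scans of 400 A-scans (460 blocks), 86-scan
evaluation panels, 200-replicate Monte-Carlo separability checks on
200-column scans, 10,000 bootstrap iterations, and an 8192-pixel-deep
noiseless phantom for the attenuation closed form (deep enough that
the truncated-tail bias sits below the 1e-9 comparison tolerance for
the smallest μ tested). These sizes were chosen so the whole suite
completes in seconds while every statistical tolerance retains
comfortable margin.
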