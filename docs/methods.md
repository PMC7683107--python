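# Methods

`strokesep` measures whether early ischemic lesions that are invisible to the
eye on non-contrast head CT are nevertheless *separable* — whether a
classifier can distinguish a lesion region from healthy tissue using
high-throughput texture features. Because no patient data ship with the
package, every stage runs on synthetic head phantoms with known ground
truth; this note records the models, parameters, and numerical choices, and
what the synthetic setting can and cannot show.

## Synthetic head phantom

An axial slice is an elliptical head on a 512×512 grid (0.45 mm pixels):
skull ring (700 HU), white-matter interior (25 HU), cortical gray-matter
ribbon and mirrored deep-gray nuclei (38 HU), and angled paraventricular CSF
slots (8 HU) that anchor the head's orientation. The noise-free anatomy is
explicitly symmetrized, so with zero noise the slice equals its own column
reflection bit for bit. Two stochastic layers are added:

* **correlated noise** — white Gaussian noise smoothed with a Gaussian
  kernel (`noise_corr_len`, default 1.5 px) and rescaled to `noise_sd`
  (default 5 HU), the speckle texture that second-order features respond to;
* **asymmetry jitter** — a random left/right brain-mean offset
  (SD 1 HU), because real brains are not mirror-identical.

Each subject also receives a small random in-plane pose (rotation within
±5°, shift within ±8 px), so the midline must genuinely be estimated
downstream; the generating pose is stored only for validation.

### Lesion model

A lesion is a connected blob: a circle of radius `mean_radius` (per-subject
Uniform(9, 18) px) with a random low-order Fourier perturbation of the
boundary (irregularity Uniform(0.10, 0.35), bounded so the area stays within
(1±irr)² of the disk). The effect inside the ROI is:

* a mean attenuation drop `delta_hu` (default −6 HU), applied through a
  feathered weight restricted to the ROI and normalized to mean 1, so the
  ROI-mean shift equals `delta_hu` exactly while pixels outside the ROI are
  untouched;
* texture loss: blending toward a Gaussian-smoothed copy of the slice
  (`smooth_sigma`, default 1.5 px), reducing local variance.

With `delta_hu = −6` and `noise_sd = 5` the contrast-to-noise ratio is near
1 — the "no positive finding on CT" regime the analysis is about. Setting
`delta_hu = 0, smooth_sigma = 0` yields the null cohort used for
calibration: lesion-labelled and control regions are then exchangeable by
construction.

### Cohort layout

38 lesion subjects contribute one slice each (lesion ROI = ground-truth
mask); 18 control subjects contribute three slices each, whose ROIs are
lesion-shaped masks drawn from the lesion subjects' mask library and placed
at random valid positions inside the control brain (up to 50 placement
retries). This reproduces the bookkeeping of the motivating study design:
38 lesion regions + 54 control regions, each with a mirrored counterpart.

## Midline estimation and mirroring

The symmetry axis (offset ±20 px in 1 px steps, angle ±10° in 0.5° steps) is
found by maximizing the Pearson correlation between the brain-masked slice
and its reflection across the candidate line, with ties broken toward the
smaller |angle| then |offset|. The search is hierarchical (a 2 px/2° pass on
a 4× decimated image brackets the optimum; a fine pass at 2× reaches the
stated resolution) — identical results to the exhaustive grid on phantoms at
a fraction of the cost. On 50 noisy symmetric phantoms the estimator's mean
|offset| error is 0 px.

ROI mirroring reflects the mask across the line and re-binarizes by keeping
the `area` highest interpolation weights after mild (σ = 1 px) smoothing.
Two pitfalls motivated this: 0.5-thresholding systematically erodes small
convex masks (>2% area loss), and an unsmoothed rank selection produces a
ragged boundary whose texture signature separates mirrored masks from
directly rasterized ones — a leak we detected with paired t-tests on a null
cohort. For the same reason, when candidate pairs are assembled the
*original* ROI is passed through the identical smooth-and-rank operator
(area-preserving), so boundary character cannot encode which side of the
pair a region came from; with both fixes the paired t-test profile across
the 930 features is statistically indistinguishable from uniform. Mirrored
masks falling partially outside the brain are clipped; a pair keeping <50%
of its area is dropped and logged.

## Registration

The two-stage alignment (coarse rotation, then affine refinement over
translation, rotation, anisotropic scale about the image center, composition
scale→rotate→translate) optimizes normalized mutual information
(Studholme's (H(A)+H(B))/H(A,B)), the standard cross-modality similarity.
Numerical choices that mattered:

* **64 intensity bins** — 32 bins left the metric too coarse for subpixel
  recovery on phantoms;
* **Gaussian pre-smoothing of both images during optimization** (σ = 2 for
  the global stage, σ = 0.5 then raw for polishing) — the binned NMI of
  sharp-edged noise-free images is comb-like, and derivative-free search
  stalls in micro-optima without it;
* **multi-start**: a near-mirror-symmetric head admits alias optima (wrong
  rotation plus compensating shift). `register()` therefore refines from an
  anatomy-informed start (difference of the two heads' symmetry-axis angles,
  head-extent ratio for scale, FFT cross-correlation for translation) plus
  the best angle-distinct candidates of an FFT-translation scan, and keeps
  the best final metric. Powell's method, iteration cap 500, parameter
  tolerance 1e-3 (1e-4 in the polish), on a fixed parameter scaling of
  10 px / 10 px / 5° / 0.05 / 0.05 per unit.

On noise-free 256×256 phantoms, 20 random affines with |t| ≤ 10 px,
|θ| ≤ 10°, scales in [0.9, 1.1] are recovered with worst-case errors of
0.5 px / 0.2° / 0.012.

## Feature bank

930 features: 10 image transforms × (18 first-order + 24 GLCM + 16 GLRLM +
16 GLSZM + 14 GLDM + 5 NGTDM), named `<transform>_<class>_<feature>`. The
bank is an explicit registry rather than an attempt to reverse-engineer any
particular historical feature count; it is configurable and the default is
documented here.

* **Transforms**: identity; four single-level *stationary* Haar wavelet
  subbands (the undecimated transform is shift-invariant — decimated
  subbands depend on the parity of the 2×2 grid and would systematically
  distinguish a region from its reflection); square, square root, logarithm
  and exponential applied after shifting ROI intensities to ≥ 1 (CT values
  are negative) and rescaled linearly back to the ROI's original intensity
  range, so a fixed bin width stays meaningful; gradient magnitude (central
  differences).
* **Discretization**: fixed bin width of 5 HU inside the ROI (level =
  ⌊(v−min)/w⌋+1); a fixed-bin-count mode (32) is available. Matrix features
  are invariant to adding a constant because the bin origin tracks the ROI
  minimum.
* **Geometry**: features are computed on the ROI bounding box padded by
  8 px; GLCM/GLRLM use distance 1 and angles {0°, 45°, 90°, 135°}, averaged
  over angles; GLSZM zones use 8-connectivity; GLDM uses Chebyshev-1
  neighbors with tolerance 0 (dependence = count + 1); NGTDM follows the
  standard five-feature definition. Degenerate single-level ROIs take the
  usual conventions (Contrast 0, Correlation 1, entropies 0); non-finite
  values are replaced by 0 and logged.
* Shape features are deliberately excluded: lesion and mirror masks are
  congruent by construction, so shape would be either uninformative or, for
  lesion-vs-normal, a leak.

Every feature class is verified to 1e-9 against an independent brute-force
implementation (explicit pair/run/zone enumeration with Python loops) on
random small ROIs.

## Information-gain screening

For binary label Y and feature X discretized by equal-frequency binning
(k = 10; ties at bin edges go to the lower bin; k configurable, tested at
2/5/10): IG(X,Y) = H(Y) − Σₓ p(x) H(Y|X=x), in bits (log base 2, so
H(Y) = 1 for balanced classes and thresholds live naturally on [0, 0.5]).
Counts use strict inequality (IG > t). A worked value used in tests:
labels (0,0,1,1) against bins (a,a,a,b) give 1 − ¾·H(⅓) = 0.3113 bits.

IG is computed on the full table before cross-validation, mirroring the
screen-then-evaluate protocol of the motivating analysis. **This biases
post-selection accuracy upward**: the features surviving a strict threshold
are the most label-correlated of 930 candidates even under the null. On a
null cohort we measure chance-level accuracy at the operating threshold 0.1,
but ~0.66 at threshold 0.2 for the 56-row pairing — a property of the
protocol, not of the data. Every report carries this caveat; finite-sample
IG inflation (E[IG] ≈ (k−1)/(2n ln 2) bits for noise) is also why a working
threshold of 0.1 rather than 0 is used.

## Classifier evaluation

10 classifier families (scikit-learn, fixed documented defaults): MLP (one
hidden layer of 100 units, 200 iterations), decision tree, random forest
(100 trees), AdaBoost (100), gradient boosting (100), bagging (100),
Bernoulli naive Bayes on features binarized at the training-fold median,
Gaussian naive Bayes, RBF-kernel SVM (C = 1), 5-nearest-neighbors.
Features are standardized with training-fold statistics only. Splitting uses
scikit-learn's `StratifiedKFold`, or `StratifiedGroupKFold` when regions are
paired — a region and its mirror share a subject and slice and must not
straddle folds. (A hand-rolled splitter that made every training fold
exactly class-balanced measurably biased null accuracies and was replaced.)

Accuracy is the pooled fraction correct per test fold, averaged over 4 folds
× `repeats` repeats (default 100; the test and acceptance profile uses 10,
at which the Monte-Carlo SE of a grid cell is well under 0.02 on 76-row
tables). The report contains the classifier × threshold grid, per-threshold
averages over classifiers, the headline average (mean of per-threshold
averages over thresholds ≥ 0.1), the same mean over all evaluated
thresholds, the best cell, and (clearly marked as an extension) balanced
accuracy per threshold for the imbalanced lesion-vs-normal pairing.

Three pairings are evaluated: lesion vs mirror (76 rows, paired), normal vs
mirror (108 rows, paired — the negative control), lesion vs normal (56
unpaired rows, one slice per control subject).

## What the synthetic setting shows — and what it does not

Passing tests establish that the pipeline is internally sound: the
statistics match independent oracles, geometry and registration recover
known ground truth, a null cohort yields chance accuracy at the operating
threshold, and an effect cohort with a near-invisible lesion yields
above-chance separability with more surviving features for lesion pairings
than for the control pairing. They do **not** establish clinical
performance: the phantom lacks anatomical variability between subjects,
partial-volume and beam-hardening physics, real lesion morphology, and the
demographic differences between patient groups that a real cohort carries.
One consequence is concrete: with a generator in which mirrored tissue and
control tissue are statistically identical, lesion-vs-normal enjoys no
structural advantage over lesion-vs-mirror, whereas in patient data the
lesion and control groups differ systematically (e.g., in age), which is
part of why lesion-vs-normal separability is reported highest there.

## Problem sizes

The default pipeline (`run_all`) and the acceptance script use the reference
cohort (38 + 18 subjects, 92 slices, 184 regions, 930 features) with the
reduced 10-repeat cross-validation profile; `--repeats 100` in
`analysis/05_evaluate_separability.py` reproduces the full protocol.
Unit tests run miniature cohorts (≤ 8 subjects) and 256×256 phantoms.
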