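# Methods

`rsoct` reimplements, end to end, a multimodal ex vivo discrimination analysis
for colorectal biopsies measured with two fiber-probe modalities: single-point
Raman spectroscopy (RS) and volumetric OCT reduced to enface images. Because
no public dataset accompanies the analysis, a synthetic cohort generator is a
first-class part of the package; it emulates the statistical structure the
method assumes, and all quantitative claims in the test suite are claims about
that generator's output, not about clinical data.

## Data model

The study hierarchy is subject → sample (biopsy) → record (one measurement).
Labels live at the sample level; a tumor-labelled biopsy is typically mixed
tissue, so its individual measurement sites may be healthy-like. The package
distinguishes a record's *label* (inherited from its sample) from its *latent*
class (what tissue the probe actually saw). This distinction is what makes
record-level classification intrinsically noisy and what the sample-level
Bayes fusion is designed to overcome.

## Synthetic cohort generator

Defaults reproduce the study scale: 27 subjects, 61 samples (21 healthy /
40 tumor), ~303 RS records and ~346 OCT records in total, with per-sample
record counts drawn as 1 + Poisson(mean − 1).

**Raman records** are pseudo-Voigt mixtures (Lorentzian fraction 0.3, FWHM
16–30 cm⁻¹) at twelve assigned colon-tissue bands (853, 935, 1078, 1265,
1302, 1451, 1661, 2860, 2890, 2935, 3010, 3210 cm⁻¹) on a 1024-channel axis
spanning 600–3300 cm⁻¹. Records sit on a jittered quadratic-plus-broad-
Gaussian autofluorescence baseline, are multiplied by a smooth positive
instrument-response curve, and carry heteroscedastic (shot-like) noise plus
Bernoulli(0.1) cosmic spikes of 1–3 channels at 20–60× the local noise sd.
Class contrast: tumor-like tissue shifts band amplitudes by
`weight × rs_effect_size × noise_sd`, with protein bands up and lipid bands
down; the broad water band at 3210 cm⁻¹ is deliberately class-independent.
Subject- and record-level log-normal amplitude factors (sd 0.08 / 0.05) make
subject-wise validation meaningfully different from record-wise.

**OCT enface records** are isotropic speckle (squared magnitude of a smoothed
complex Gaussian field, correlation length 2 px) for healthy-like sites;
tumor-like sites add an oriented band-limited component — white noise
filtered by a Gaussian annular sector in the Fourier plane at 0.08
cycles/pixel and a random wave-vector angle — emulating the oriented fibrous
(desmoplastic) texture of tumor stroma. Images are min-max scaled to [0, 1];
default geometry is 500 px at 4 µm/px (2 mm field of view).

**Heterogeneity.** Each tumor sample draws a purity uniformly from [0.1, 1];
each of its records is tumor-like with that probability. With the default
range, roughly 45% of tumor-labelled records are healthy-like, which caps the
achievable record-level AUC near 0.78 even when the latent classes are
perfectly separable — the same record-vs-sample structure the method is built
for. Healthy samples have purity 0 and never contain tumor-like records.

The generator does **not** emulate: OCT speckle physics or the interferogram,
depth-dependent signal decay, instrument drift, histology. Passing tests
therefore demonstrate the pipeline's statistical behaviour under the stated
generative assumptions, not clinical performance.

## Raman preprocessing

Fixed stage order: cosmic-spike removal → wavenumber calibration →
intensity-response correction → batch SVD denoising (rank 30) → ALS baseline
removal (λ = 10³, p = 10⁻⁵, 10 iterations, second-difference penalty solved
as a symmetric banded system) → EMSC against the batch-mean reference with
optional known interferents and a quadratic polynomial → area normalization
(unit trapezoidal integral) → per-channel Welch t-test band selection
(two-sided p < 10⁻¹⁰; maximal contiguous runs reported as regions).

Numerical choices: spike detection uses a robust (median/MAD) z-score of the
first differences with threshold 8, flagging only up-then-down crossing pairs
within 3 channels, so broad Raman bands never trigger it; flagged channels
are repaired by linear interpolation from the nearest unflagged neighbours
and every other channel is returned bit-identical. Calibration fits a
degree-5 channel→wavenumber polynomial and requires at least 7 matched
reference peaks and a monotone mapping. The whole batch is preprocessed
together (matching the published single-batch processing); this implies the
Welch selection sees all labels before cross-validation — a deliberate
fidelity choice, noted here because it is a mild leakage channel for the
record-level feature selection step. If no channel survives the significance
threshold (as happens under null effect sizes), the pipeline falls back to
the full spectrum so validation still runs.

## OCT texture descriptors

Four blocks per image, in fixed order:

* **Gabor** — filters defined in the Fourier plane as one-sided Gaussian
  annular sectors, four centre frequencies one octave apart from 0.4
  cycles/pixel, six orientations (0°–165° in 33° steps), 30° FWHM angular
  bandwidth, σ_r ≈ 0.3 f_c; DC bin zeroed, making features exactly invariant
  to intensity offset. Features: mean and sd of the response magnitude per
  filter (48 values).
* **LBP** — rotation-invariant uniform patterns at radii 1/2/3 with 8/16/24
  neighbours; per scale, the normalized P+2-bin histogram plus the mean of
  the local variance map. Images are quantized to 256 gray levels first.
* **LPQ** — 7-px uniform-window short-time Fourier transform at the four
  lowest non-zero frequencies; 8-bit sign codes of the real and imaginary
  parts; 256-bin normalized histogram. Implemented from scratch (no library
  implementation exists in the stack); verified against a brute-force
  windowed-DFT oracle.
* **GLCM** — asymmetric normalized co-occurrence matrices at distance 5 and
  angles 0°/90°/180°/270°, 256 levels; contrast, dissimilarity, homogeneity,
  energy, correlation and angular second moment per angle (24 values).

## Classifier validation

All validation is leave-one-subject-out (LOSO); the subject is the highest
hierarchical level, which eliminates identity confounding between partitions.
Per outer fold: Z-score standardization and PCA are fitted on training rows
only (RS: 10 components on the Welch-selected channels; OCT: 10 components
per texture block, standardized and reduced separately, scores concatenated
to a 40-dim composite). The classifier is LDA, tuned by nested LOSO over the
training subjects on a 3 × 7 grid (solver ∈ {svd, lsqr, eigen} × tolerance ∈
{10⁻², …, 10⁻¹⁴}) with mean inner-fold AUC as the merit; one-class inner
folds are skipped, ties go to the first configuration in grid order, and
configurations whose scatter matrix is singular are unscorable. Since the
tolerance only affects the svd solver, the grid collapses to 9 distinct fits
per fold, which are cached. Held-out predictions of all folds are pooled
into a single ROC per modality.

LDA class priors are fixed at (0.5, 0.5). The fusion stage assumes a 0.5
sample prior and applies one fixed decision threshold across folds, which
requires fold-to-fold comparable posterior levels; empirical priors would
tie each fold's posterior level to its training class balance (and
measurably bias pooled null AUCs below 0.5).

Operating points on a ROC: Youden (max TPR − FPR, ties to lowest FPR);
confirmatory / C-test (max TPR subject to FPR ≤ 0.1); screening / S-test
(first point with TPR ≥ 0.9). Confusion statistics are reported both as exact
fractions and rounded half-up to two decimals; ratios with zero denominator
are reported as undefined, never as 0.

## Sequential Bayes fusion

Each record is a binary diagnostic test at a fixed threshold. A sample's
tumor probability starts at 0.5 and is updated once per record:
positive → p' = TPR·p / (TPR·p + FPR·(1−p));
negative → p' = 1 − (1−FPR)(1−p) / ((1−FPR)(1−p) + (1−TPR)·p).
Both are prior-odds × likelihood-ratio updates, so the result is invariant to
update order and equals the closed-form odds product. RS updates are applied
before OCT updates (order is provably irrelevant; the log preserves it).
Rates are clipped to [10⁻³, 1−10⁻³] so no fold can produce an absorbing 0/1
posterior. A numerical note: probability-space sequential updating loses
absolute precision beyond ~10⁻¹² once intermediate odds exceed ~10³, because
1 − p collapses in float64; the closed-form product is exact in odds space.

Two estimation choices were genuinely open and are resolved as follows:

* **Fixed thresholds.** The published per-modality thresholds (0.56 RS,
  0.73 OCT) are that cohort's single-modality Youden values. On synthetic
  cohorts the pipeline derives each modality's fixed threshold the same way —
  the Youden point of the record-level pooled validated ROC — then holds it
  fixed across all fusion folds. `run_combined_validation` keeps literal
  0.56/0.73 defaults for direct use.
* **Per-fold operating rates.** The TPR/FPR entering each update are
  estimated from the *held-out* inner-LOSO predictions of the fold's training
  subjects at the fixed threshold, not from refit training predictions: a
  tuned LDA at these sample sizes separates its own training set almost
  perfectly, so refit rates saturate at the clip bounds and give every
  record a likelihood ratio of ~10³, letting a weak modality swamp a strong
  one. Inner-CV rates use only training-subject data and are honest
  estimates of test-time behaviour.

Single-modality fusion modes (RS-only, OCT-only) run the identical procedure
with the other modality's update list empty.

## Problem sizes used in the automated checks

The test suite exercises the end-to-end behaviour on a reduced cohort chosen
to keep the full suite within a routine CI budget: 20 subjects, 44 samples
(15 healthy / 29 tumor), ≈200 RS and ≈220 OCT records, 128-px enface images,
10 seeds for the fusion-dominance check and 5 seeds (averaged) for the
null-calibration check. At 44 samples a single null AUC has sd ≈ 0.09, so
calibration is asserted on the seed-averaged AUC. The acceptance script runs
the full 27-subject / 61-sample cohort with 256-px images (the generator's
texture statistics do not depend on the image side; 500-px images only slow
the texture stage).

## Known limitations

* The generator's class contrast is stylized (fixed band-shift directions, a
  single fibrous orientation per image); real tissue contrast is richer.
* Batch-level SVD denoising and Welch selection see the whole dataset before
  splitting, mirroring the published processing; a per-fold variant is not
  implemented.
* Sample-level AUCs on ~44–61 samples carry sampling noise of several
  hundredths; single-seed comparisons between fusion modes are accordingly
  noisy, which is why multi-seed majorities are used.
* Records within a sample are treated as conditionally independent tests
  given the sample's class, as the update rule assumes; in the generator (and
  in tissue) they are correlated through purity, so posteriors are
  over-confident in both directions. This is a property of the method being
  reimplemented, not a defect of the implementation.
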