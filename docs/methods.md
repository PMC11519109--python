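# Methods

`diagqm` quantifies what accelerated-MRI reconstruction does to *diagnosis*,
not just to image appearance.  The pipeline mirrors a clinical evaluation
study: T2-weighted prostate volumes are retrospectively undersampled in
k-space, reconstructed naively or with a learned model, fed to a lesion
detector that emits voxelwise likelihood heatmaps, and the conditions are
compared with visual-quality metrics (SSIM/PSNR) against a
diagnostic-quality metric (the partial area under the FROC curve) plus a
statistics battery.  This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic phantoms can and
cannot show.

## Retrospective undersampling

Acquisition is accelerated by omitting phase-encoding lines.  The binary
line mask keeps `round(n_lines / R)` lines (round half away from zero; R is
the acceleration factor, so R4 keeps 25% of k-space).  A contiguous band of
`round(0.20 x budget)` lines around the DC line is always included — the
low-frequency centre carries most signal energy — and the remaining lines
are drawn without replacement from the periphery with inclusion weights
`exp(-distance / scale)`.  The 20%/80% centre/periphery split is the
default (`central_fraction`); the exponential decay scale has no standard
value, so it is exposed in `MaskConfig` with a default of
`n_lines / 6`, chosen so the density taper is visible while the outermost
lines remain reachable.  The weighted draw uses Efraimidis–Spirakis
reservoir keys, so a mask is a pure function of `(n_lines, config)`.

Tie-breaks are fixed and documented: budgets round half away from zero; the
central band of even length places its extra line on the +k side.  For
zero-filled acquisitions, `pad_mask_for_zero_fill` extends the mask with
never-sampled outer lines, DC lines aligned, mirroring the zero-filling the
scanner applies to the data.

Undersampling operates per 2D slice on magnitude images: FFT with DC
centred, multiply by the mask broadcast across the frequency-encoding axis,
undo the shift, inverse FFT, take the magnitude.  Phase is zero by
construction (the inputs are magnitude DICOM-derived images), which is the
accepted single-coil image-space simulation; multicoil/complex k-space
synthesis is out of scope.  Slices are never undersampled in the
through-plane direction.  With R=1 the operation is the identity to
floating-point tolerance, which the tests pin against an explicit
O(N^4) DFT-summation oracle.

## Synthetic phantom cohort

Because the clinical scans are not redistributable, a seeded generator
produces prostate-like volumes so every downstream stage is testable:

* an ellipsoidal gland with a bright peripheral zone (intensity 0.85) and a
  darker transition-zone core (0.60) in dim background tissue (0.20), with
  smooth logistic margins;
* optional hypointense lesions: ellipsoids fully inside the gland,
  radius 3.5–7 mm, with a 40% relative signal drop and smooth margins; the
  labelmap records the hard ellipsoid, and the sampled geometry is kept on
  the case for volume checks;
* an oriented high-spatial-frequency texture (sharp along the
  phase-encoding axis, smoothed along the others) so undersampling visibly
  blurs one axis;
* a smooth multiplicative bias field (coil-profile-like ramp, 10%);
* Rician noise — the magnitude-MR noise model — at sigma = 3% of the
  peripheral-zone intensity.

Lesion prevalence defaults to 0.48, matching the roughly-half-positive
composition of the multicentre cohort the package emulates, with 1–3
lesions per positive patient.  Cases carry a site label drawn with weights
305/384/846 so splitting behaves like a three-centre study.  Per-case
generators are derived from the master seed by a counter-based scheme
(`SeedSequence((seed, index))`), making cohorts prefix-stable in n.

The default grid is (160, 160, 16) voxels at (0.5, 0.5, 3.0) mm — the
detection-stage grid, so preprocessing is near-identity on phantoms.  Test
and example runs use smaller grids, typically (96, 96, 12) at
(1.0, 1.0, 3.0) mm, which keeps a 46-case end-to-end run in minutes on one
CPU core; the methods and defaults do not change with grid size.

What the phantoms do *not* emulate: real anatomy (no urethra, capsule,
seminal vesicles, rectum), heterogeneous zonal texture, PI-RADS-grade
appearance differences, motion or susceptibility artefacts, or scanner
variability.  A green phantom suite shows the machinery is correct and the
orderings are recoverable under controlled degradation — not that a
particular clinical effect size would replicate.

## Preprocessing chains

Two fixed chains reproduce the two model front-ends: the reconstruction
chain resamples in-plane to 0.5 x 0.5 mm (z unchanged, nearest-neighbour),
centre-crops to (256, 256, 16) and min/max-normalises to [0, 1]; the
detection chain resamples to (0.5, 0.5, 3.0) mm, crops to (180, 180, 16)
and z-normalises.  Crop sizes are arguments so desk-scale grids pass
through unchanged.  Odd crop/pad margins put the extra voxel on the
high-index side; labelmaps always travel through the same geometry with
nearest interpolation so they stay integer and voxel-aligned.  A sigma
floor of 1e-8 protects z-normalisation of constant (fully padded) inputs;
min/max of a constant volume returns zeros.  Undersampling happens at
native resolution, before resampling.

## Models

The reconstruction and detection stages are contracts, not fixed
architectures: anything mapping volume to volume (or volume to heatmap) on
the same grid plugs in.  The shipped desk-scale defaults are small
two-level convolutional encoder–decoders with a skip connection, written
in numpy with hand-derived backpropagation (verified against finite
differences in the test suite) and Adam.

* **Reconstructor** — residual: `output = clip(input + net(input), 0, 1)`;
  the head is zero-initialised so the untrained model is the identity.
  Loss is `1 - mean SSIM` with the same 11-tap Gaussian window and
  constants as the evaluation metric; the analytic SSIM gradient
  propagates through the filtered moments (the zero-padded symmetric
  Gaussian is self-adjoint, and the border-cropped mean makes the value
  independent of the padding mode).  Reference protocol hyperparameters:
  batch 12, Adam, learning rate 4e-4, early stopping on a held-out split;
  augmentations rotation (p=0.25, ±30°), additive input noise (p=0.60,
  sd up to 0.003), mirroring (p=0.50), applied during training only.  At
  desk scale the experiment defaults raise the learning rate to 2e-3 —
  appropriate for a model several orders of magnitude smaller than a full
  3D U-Net.
* **Detector** — sigmoid head, per-voxel weighted binary cross-entropy with
  class weights 0.05 (background) / 0.95 (lesion); augmentations rotation
  (p=0.10), noise (p=0.30, up to 0.001 of the instance sd), horizontal
  flip (p=0.50).  Training runs five-fold cross-validation inside an 80%
  development split; the best epoch per fold is kept by validation loss,
  and inference averages the fold models voxelwise.  Detectors are trained
  on fully sampled images and **never retrained per acceleration** —
  retraining would let the model normalise reconstruction hallucinations
  and hide exactly the effect being measured.
* **Surrogate detector** — a deterministic, training-free stand-in used by
  the evaluation-focused tests and the default experiment: multi-scale
  centre-surround evidence (surround-minus-centre Gaussian differences at
  1.5/2.5/4 mm, surround = 2x centre) responds to voxels darker than their
  neighbourhood, is divided by a contrast scale (0.3) and clipped to
  [0, 1].  It is monotone in lesion contrast below saturation and returns
  a zero map on constant input (responses under 1e-9 are floored to kill
  filter round-off).

## Candidate extraction, matching, FROC

Heatmaps become candidates by peak-wise extraction: every local maximum
above a floor (0.10) seeds a watershed basin of the likelihood field
(26-connectivity, masked at the floor); peaks are visited in descending
height, each contributing the part of its basin above 0.40 x peak as a
candidate region with the peak value as confidence.  Watershed ownership
is what makes the procedure well-behaved at both extremes: a smooth blob's
tail cannot re-surface as a duplicate rim candidate, and two nearby
lesions that share territory at the floor still yield separate candidates.
Regions under 3 voxels are dropped; extraction stops at 10 candidates.
All four numbers are exposed in `CandidateParams`.

Matching is greedy in descending confidence: a candidate claims the
unmatched lesion with the highest overlap provided the overlap reaches 10%.
Overlap is intersection-over-union (symmetric; a fraction-of-lesion variant
sits behind a flag).  Candidates whose only sufficient overlap is with an
already-claimed lesion are *discarded* — neither TP nor FP — the standard
FROC treatment of split detections; everything else is a false positive,
and unclaimed lesions are misses.

The FROC curve sweeps the confidence threshold over all observed values.
Because greedy matching processes candidates in confidence order, its
decisions for the top-k candidates are identical whether or not weaker
candidates exist; each patient is therefore matched once and the sweep
reads cumulative TP/FP prefixes.  The suite verifies exact equivalence
with a brute-force oracle (exhaustive thresholds, exhaustive assignment
enumeration) on small cohorts.  Sensitivity is cohort-level (hit lesions /
all lesions); the FP rate averages over all patients including lesion-free
ones.

The diagnostic-quality summary is the trapezoidal integral of sensitivity
over FP/patient on the **linear** axis restricted to 0.1–2.5 FP/patient
(display plots use a log axis; the integral does not).  The curve is
interpolated linearly between operating points and from the (0, 0) origin,
and extended right-constant past the last point; the perfect detector
scores the window width 2.4.  Confidence intervals come from patient-level
bootstrap resampling (percentile; degenerate lesion-free resamples are
redrawn and counted).

## Statistics

* **Wilcoxon signed-rank** (paired SSIM comparison): zero differences
  dropped; up to n = 25 the exact two-sided p is computed from the
  sign-flip null distribution via dynamic programming over doubled
  midranks, which handles tied magnitudes exactly (the all-equal
  five-pair fixture gives p = 0.0625); above that, the tie-corrected
  normal approximation.
* **Permutation test** on a pAUC difference: the pairing unit is the
  patient; the null swaps each patient's two condition labels
  independently and recomputes both pAUCs.  When 2^n fits in the
  permutation budget the null is enumerated exactly
  (p = #{|null| ≥ |obs|} / 2^n, which is never 0); otherwise it is
  sampled with the add-one estimator (1 + count) / (n_perm + 1).
* **Patient-level ROC**: a patient's score is the maximum candidate
  confidence (0 when no candidates) — the convention in the csPCa
  detection literature.  AUC is the tie-corrected rank statistic.  The
  operating threshold is the Youden-index maximiser *on the reference
  condition* and is then held fixed when scoring degraded conditions, so
  sensitivity/specificity/PPV/NPV shifts are attributable to the
  reconstruction, not to re-thresholding.
* **Cohen's kappa** for reader concordance: three-category ratings
  ({consistent, minor variation, inconsistent}) collapse to binary with
  the minor-variation class counted as consistent (the 3x3 unweighted
  table is available); the CI is the standard asymptotic variance
  (statsmodels).  Degenerate marginals (chance agreement 1) return a
  kappa-0 sentinel.  Candidate cases for a reader study are selected as
  the top-k / bottom-k patients by |reference score − condition score|,
  ties broken by patient id.

## Splitting

The 80/20 development/test split is stratified by acquisition site, with
the training side receiving the per-site ceiling of the fractional count;
for the emulated three-site composition (305/384/846 = 1535 patients) this
gives 1229 development and 306 held-out patients.  Development patients
are partitioned into five disjoint folds (round-robin over a seeded
shuffle).  The manifest (patient, site, role, fold) is emitted with every
experiment, and the no-leakage property is asserted in the tests.

## Experiment runner and reproducibility

`run_experiment` executes every (acceleration, method) condition —
reference R1, naive zero-filled IFFT, learned reconstruction — computes
per-case SSIM/PSNR against R1, FROC/pAUC with bootstrap CI per condition,
permutation tests against R1, and the patient ROC at the R1-derived
threshold, all on the held-out test patients.  Masks are seeded per
patient, every stochastic step derives from the experiment seed, and the
report carries a provenance record (SHA-256 config hash, seed, package
version) sufficient to re-run bit-identically; re-running a config is
asserted to reproduce the summary exactly.

`scripts/acceptance.py` re-runs this end to end at desk scale (60 cases on
the (96, 96, 12) grid, a 50/50 split so the 30-patient evaluation side
gives the permutation test resolving power, 10 training epochs, 100
bootstrap / 400 permutation draws) and writes the headline numbers as
JSON.

## Known limitations

Desk-scale networks are two-level 2D encoder–decoders, not the 3D U-Nets
(with attention and squeeze-excitation options left off by default) a
GPU-scale study would train; they demonstrate the evaluation framework,
not state-of-the-art reconstruction.  The k-space simulation is
single-coil magnitude-image based.  pAUC values on clean phantoms sit high
in the 0–2.4 range (the R1 surrogate detector is near-ceiling); the
orderings and test behaviour, not the absolute pAUC level, are the
meaningful output at desk scale.  SSIM is computed slice-wise and averaged
(whether a volumetric variant differs is recorded per result via the
settings field).
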