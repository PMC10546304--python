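# Methods

## Problem and pipeline

`cystfuse` classifies pancreatic cystic neoplasms as serous (SCN) or
mucinous (MCN) from seven co-registered MR series per patient: six T1
dynamic contrast phases in temporal order (T1pre, T1a1, T1a2, T1v1, T1v2,
T1post) and a T2-weighted series. The pipeline is

1. resample every series onto isotropic 1 mm spacing (trilinear),
2. clip each modality to an intensity window and map it linearly to [−1, 1],
3. crop an 80-voxel cube around the annotated lesion center,
4. extract paired axial slice packs (the same z position in all seven
   modalities),
5. train a multi-branch convolutional classifier with a fusion block,
6. aggregate slice probabilities into per-patient diagnoses,
7. evaluate under stratified patient-level k-fold cross-validation.

MCN is the positive class throughout, and predictions threshold p(MCN) at
0.5 with exactly 0.5 mapping to MCN (the clinically conservative choice:
MCN is the lesion type with malignant potential).

## Synthetic phantom generator

The phantom generator defines the package's study conditions; nothing
downstream is tuned to it.

**Geometry (the shared content).** Lesions are built from analytic solids so
the ground truth is checkable voxel-by-voxel: SCN lesions are clusters of
2–5 overlapping ellipsoidal cysts (radius 4–8 mm, 1-voxel walls, lobulated
union contour) with a central 2.5 mm fibrous scar present with probability
0.30 — the reported prevalence of the central-scar sign in serous lesions;
MCN lesions are one dominant ellipsoidal cyst (radius 10–14 mm) with an
uneven 2–4 voxel wall, 1–3 mural nodules and 1–2 planar septations. The
region map (background / fluid / wall / septation / nodule / scar) is
returned as ground truth.

**Appearance.** All seven modalities of one phantom share the identical
region map; only the intensity lookup differs. Cyst fluid is dark on T1
(40) and bright on T2 (250) against a tissue level of 100 (arbitrary
units — no quantitative per-modality intensities are published for this
problem, so the scales are free parameters chosen once for plausible
contrast ordering). Wall-type tissue ramps monotonically over the six T1
phases with a class-dependent slope: by default 110→150 for SCN and
110→235 for MCN, encoding the strong delayed enhancement of mucinous
walls, nodules and septations; scar tissue enhances mildly and is dark on
T2. A smooth multiplicative-free bias field (amplitude 10) and white
Gaussian noise (sd 4) are added; an optional rigid per-modality translation
(default off) emulates imperfect inter-series alignment.

**Spacing.** Volumes are generated on a 128×128×36 grid at anisotropic
spacing drawn per phantom from abdominal protocol ranges (T1 in-plane
0.78–1.04 mm, axial 2.50–2.59 mm; T2 in-plane 0.625–0.88 mm, axial
4.80–8.40 mm), so the resampling stage is genuinely exercised and T2 has
the coarse axial sampling typical of fast spin-echo acquisitions.

**Controlled signal planting.** `planted_t1post_config()` produces a
configuration with class-neutral geometry (one spherical cyst for both
classes) and wall ramps that coincide on every modality except T1post.
Any class signal then lives exclusively in the T1post appearance, which is
how the tests verify that the pipeline attributes discriminative power to
the correct modality.

**What the phantoms do not emulate.** No anatomy (pancreas, duct, vessels),
no MR physics (k-space, TE/TR, coil profiles), no calcification, and the
per-modality intensity scales are synthetic. Passing tests on phantoms
demonstrates that the machinery (preprocessing, fusion, training,
aggregation, evaluation) is correct and that planted signals are recovered;
it does not demonstrate clinical performance on patients.

## Preprocessing choices

- Resampled dimensions are `round(dims × spacing)` with round-half-away-
  from-zero; interpolation is separable trilinear, edge-clamped.
- Windows: real scanner exports span roughly −1700 to 2048, and published
  window settings per modality do not exist, so the default window is
  derived per volume from the 0.5th/99.5th percentiles of nonzero voxels
  (robust to outliers, scale-free). A fixed window can be supplied instead;
  `phantom_window_spec()` (0–300 on all modalities) is the natural choice
  for phantoms because per-volume percentile windows partially normalize
  away absolute between-class intensity differences — exactly the behaviour
  fixed per-modality windows avoid on real data.
- The crop covers `[c − 40, c + 40)` per axis; out-of-volume voxels are
  filled with −1, the post-normalization background value. Because each
  modality is resampled from its own native spacing, the lesion center is
  rescaled per modality before cropping.
- Slice packs: `k_slices` consecutive axial positions centred at z = 40.
  The default is 27 per patient (≈ the published dataset's 1835 packs / 69
  patients; the paper-internal slice bookkeeping is inconsistent, so the
  package records its own counts); the desk-scale experiments use 3.
- Augmentation applies one geometric draw (horizontal/vertical flips,
  rotation within ±15°) identically to all seven slices — inter-modality
  correspondence is content, so geometry must move jointly — plus
  independent per-modality intensity jitter (scale 0.95–1.05, shift ±0.05,
  re-clipped), since appearance is modality-specific. Whether the original
  study used intensity transforms is unstated; jitter defaults are mild and
  can be disabled (`AugmentSpec.identity()`).

## Networks and training

Two backbones are provided: `tiny` (three conv blocks on the native 80×80
slice, global average pooling to a configurable D, default 16) for
desk-scale work, and `alexnet-conv` (the five-conv-block AlexNet body on a
224×224 bilinear resize of the slice replicated to three channels, global
average pooling to D = 256). Each modality has its own backbone weights by
default — the disentanglement model assumes modality-specific appearance —
with a shared-weights mode available. IMG-F uses a single backbone with a
fresh 7-channel first convolution and has no secondary outputs (pre-trained
3-channel kernels would not transfer to a 7-channel input). Weights can be
initialised from an `.npz` checkpoint; no pre-training is bundled or
required.

The constraint losses are this package's definitions (no closed forms are
published): content consistency is the mean squared deviation of the seven
content vectors from their mean, normalized by `7·(D − L_a)`; appearance
separation is the mean squared cosine over the 21 unordered pairs
(bounded in [0, 1], zero-vector pairs count 0). Both are pluggable. The
total objective is
`CE(main) + λ_aux Σ_m CE(secondary_m) + λ_c L_content + λ_a L_appearance`
with defaults (1.0, 0.1, 0.1); cross-entropy clamps probabilities at 1e-12.

Optimisation is Adam (default lr 1e-3, batch 8). Everything is numpy with
explicit backprop, so a fixed seed reproduces training bitwise; the
per-epoch loss trace is evaluated on the full training set after each
epoch. Gradients of every layer and of both constraint losses are verified
against central finite differences in the test suite. For the desk-scale
planted-signal experiments the learning rate is 2e-3: small enough that the
epoch-wise training loss is non-increasing across seeds, large enough to
recover the planted signal within ten epochs.

## Patient-level aggregation

Slice votes threshold at 0.5; patient majority voting breaks exact ties by
the mean p(MCN), with exactly 0.5 mapping to MCN. The SVM aggregator — the
published approach names the classifier but not its inputs — uses a
9-statistic summary per patient (mean, sd, min, max, median, 25th/75th
percentile, fraction of slices above 0.5, log(1 + n_slices)), standardized
and fed to an RBF SVM (C = 1, gamma = "scale"). The scaler and SVM are fitted
on training-fold patients only; the decision-function score provides the
patient-level ROC.

## Evaluation

Confusion counts, sensitivity, specificity and accuracy follow the printed
definitions with MCN positive; metrics with empty denominators are reported
as missing and excluded from fold means (never zero-filled). AUC is a full
threshold sweep with trapezoidal integration, tested to agree with the
brute-force pairwise Mann–Whitney statistic to 1e-12 including ties.
`make_folds` shuffles within class and deals round-robin, so per-fold class
counts deviate from proportionality by at most one patient (a 33/36 cohort
at k = 4 gives folds of 18/17/17/17 with 9/8/8/8 SCN and 9 MCN each).
Fold aggregates report mean, sample sd, min and max; published tables are
ambiguous between "±sd" and ranges, so both are printed. Cohort summaries
use Welch's t (age), continuity-corrected chi-square (sex) and
Mann–Whitney U (size); these are package defaults — the original table
names no tests — and are flagged as such in the output.

## Problem sizes used in the checked experiments

The end-to-end checks run 40-patient phantom cohorts (20/20), 3 slices per
patient, the tiny backbone (D = 16, L_a = 8), 10 epochs, 2 folds and 3
seeds; the scar-prevalence check uses 1000 phantoms. These sizes were
chosen as the smallest at which the planted-signal and aggregation
behaviour is stable across seeds.

## Known limitations

- The clinical tables of the source study were measured on a private
  69-patient cohort and cannot be reproduced here; all quantitative checks
  are phantom-based or algebraic.
- Phantom realism is deliberately limited (see above); transfer of any
  performance number to patient data is out of scope.
- The numpy networks are CPU-bound and sized for desk-scale experiments,
  not for full-resolution clinical training runs.
- DWI is excluded (as in the source protocol selection), and automatic
  lesion detection is out of scope — lesion centers are inputs.
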