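# cystfuse

Multi-modality MRI fusion for classifying pancreatic cystic neoplasms:
serous (SCN, mostly benign) versus mucinous (MCN, malignant potential).
The distinction drives the resection decision, but the two lesion types can
look alike on any single MR series; the diagnostic signal is spread over the
dynamic contrast-enhanced phases and the T2-weighted series. `cystfuse`
implements a seven-modality deep-fusion pipeline — per-modality
convolutional features, five fusion strategies including feature
disentanglement, auxiliary per-modality outputs, slice-to-patient
aggregation, and stratified patient-level cross-validation — together with a
synthetic seven-modality lesion phantom generator so the entire pipeline is
testable without patient data.

Intended users: researchers in medical image analysis who want a
reference implementation of feature-disentanglement fusion and a controlled
synthetic testbed for multi-modality aggregation experiments.

## The model

Each patient contributes seven co-registered 3D series
(T1pre, T1a1, T1a2, T1v1, T1v2, T1post, T2). After isotropic 1 mm
resampling, per-modality window normalization into [−1, 1] and an 80-voxel
lesion-centred crop, each axial position yields a *slice pack* of seven
paired 80×80 slices. A convolutional backbone per modality maps slice *m*
to a feature vector *f_m* ∈ ℝ^D, and a fusion block combines the seven
vectors before a two-layer fully-connected softmax classifier:

- **SUM** — Σ_m f_m, **MAX** — elementwise max, **CAT** — [f_1; …; f_7];
- **DIS** (feature disentanglement) — each f_m is split into a
  modality-specific *appearance* part a_m = f_m[0:L_a] and a shared
  *content* part c_m = f_m[L_a:D]; the fused vector is
  [a_1; …; a_7; Σ_m c_m] of length 7·L_a + (D − L_a). Training adds a
  content-consistency penalty (variance of the c_m around their mean) and an
  appearance-separation penalty (mean squared pairwise cosine of the a_m);
- **IMG-F** — image-level (early) fusion of the seven slices as a 7-channel
  input to a single backbone.

Per-modality *secondary outputs* (a classifier head on each f_m alone)
supervise the branches and provide single-modality evaluation. Slice-level
probabilities are aggregated per patient by majority voting or by an RBF-SVM
over a 9-statistic summary of the patient's slice scores. MCN is the
positive class: sensitivity = True-MCN/(True-MCN + False-SCN), specificity =
True-SCN/(True-SCN + False-MCN); AUC is computed by a full threshold sweep
and equals the pairwise Mann–Whitney statistic. Evaluation uses stratified
patient-level k-fold cross-validation (all slices of a patient stay in one
fold; class ratios preserved to ±1 patient).

The networks are implemented in pure numpy (explicit backprop, Adam), which
keeps training runs bitwise reproducible from a seed.

## Worked example

Generate a 20-patient phantom cohort in which the only class-discriminative
appearance signal is planted in the delayed phase (T1post), then run a
2-fold cross-validated DIS model:

```python
import cystfuse as cf
from cystfuse.phantoms import phantom_window_spec, planted_t1post_config

cohort = [s for s, _ in cf.generate_cohort(10, 10, planted_t1post_config(seed=0))]
result = cf.run_experiment(
    cohort,
    cf.ModelConfig(backbone="tiny", D=16, method="DIS", L_a=8, hidden=32),
    cf.TrainConfig(epochs=10, batch_size=8, learning_rate=2e-3, seed=0),
    k=2, seed=0, k_slices=3, patient_method="svm",
    window=phantom_window_spec(),
)
print(result.reports["T1post"].summary())
print(result.reports["patient_svm"].summary())
```

Output (metrics as mean ± sd [min, max] across the two folds):

```
T1post (single modality):
sensitivity: 0.700 ± 0.424 [0.400, 1.000]
specificity: 0.500 ± 0.707 [0.000, 1.000]
accuracy: 0.600 ± 0.141 [0.500, 0.700]
auc: 1.000 ± 0.000 [1.000, 1.000]

patient level (SVM):
sensitivity: 1.000 ± 0.000 [1.000, 1.000]
specificity: 0.700 ± 0.141 [0.600, 0.800]
accuracy: 0.850 ± 0.071 [0.800, 0.900]
auc: 0.860 ± 0.028 [0.840, 0.880]
```

The secondary output of T1post — the channel carrying the planted signal —
ranks the validation slices perfectly (AUC 1.0) even though its hard
accuracy at threshold 0.5 is mediocre after only ten epochs, and the
patient-level SVM aggregation of the fused DIS output reaches 0.85
accuracy. The same pipeline runs from the shell:

```bash
cystfuse phantoms --n-scn 10 --n-mcn 10 --seed 0 --out cohort/
cystfuse crossval --config config.yaml --manifest cohort/manifest.csv --out results/
cystfuse run-all --config config.yaml
```

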