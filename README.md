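# apneapsg

Per-minute sleep-apnea detection from five-channel polysomnography (PSG),
for researchers working on automated sleep-disordered-breathing screening
from physiological time series.  The package implements a two-stage hybrid
feature-selection pipeline:

1. **Extract** 87 time-, frequency-domain and non-linear features per
   annotated minute from ECG, SaO2, airflow, abdominal and thoracic effort
   channels — heart-rate-variability statistics (NN50, RMSSD, SDSD, …),
   ECG-derived respiration, wavelet sub-band entropies and variances,
   Welch and Yule-Walker AR spectral band means, spectral-shape
   descriptors, recurrence quantification (DET, LAM, longest diagonal),
   serial correlations, QRS (kernel) PCA, rapid-resaturation counts
   (RES4), Poincaré SD1, and effort amplitude statistics.
2. **Select** features by per-patient statistical testing: for every
   patient with both apnea (A) and normal (N) minutes, each feature gets a
   one-way ANOVA and a Wilcoxon rank-sum A-vs-N comparison.  A *positive
   pair* is ANOVA p < 0.05 together with rank-sum rejection at α = 0.05;
   λ(feature) counts positive pairs over the ν contributing patients, and
   features with λ ≥ 1 are stratified into classes A (λ = ν) … E (λ = ν−4).
3. **Evaluate** cumulative class sets A, AB, …, ABCDE with soft-margin
   SVMs (linear, polynomial (x·y+1)^d, RBF exp(−‖x−y‖²/2σ²); R ∈
   {0.2, 1, 10}, d ∈ {2, 3, 4}, σ ∈ {1, 5, 25}) under under-sampled,
   stratified 10-fold cross-validation, hill-climbing to the class set
   with the best mean accuracy.

Records can be read from WFDB-style files (`.hea`/`.dat`/`.apn`) or a CSV
dialect, and a seeded synthetic-cohort generator produces labeled PSG
records exhibiting the apnea physiology the features target (cyclic RR
variation, rapid SaO2 resaturation, airflow collapse, elevated abdominal
excursion), so the whole pipeline is testable without any download.
See `docs/methods.md` for the model details and design choices.

## Worked example

```sh
apneapsg --seed 3 --out-dir demo run-all
```

generates a default synthetic cohort (5 patients × 200 minutes), extracts
the 87-column feature table, runs the selection stage and the SVM
hill-climb, and prints

```
nu = 5; 48 features selected
chosen class set: A (29 features)
```

meaning all five patients contributed A/N test pairs, 48 of the 87
features were discriminative for at least one patient (λ ≥ 1), and the
hill-climb kept Class A — the features discriminative for *every* patient
— as the best subset.  Artifacts land in `demo/`: `features.csv` (one row
per usable minute), `selection.csv` (per-feature λ and class),
`evaluation.csv` (per class-set × kernel-config sensitivity, specificity,
accuracy and AUC).

The published per-feature λ column ships as a fixture:

```sh
$ apneapsg fixture-check
66 of 87 features selected
class A: 5 features
class B: 20 features
class C: 20 features
class D: 12 features
class E: 9 features
class A feature numbers: [2, 47, 64, 66, 77]
```

Class A here is NN50 of the RR series, the ECG spectral spread, the SaO2
rapid-resaturation count RES4, the SaO2 Poincaré SD1, and the abdominal
std of absolute excursion — each tied to a physiological signature of
obstructive apnea.

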