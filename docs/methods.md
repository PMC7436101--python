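# Methods

## Problem and pipeline

Per-minute sleep-apnea scoring from five polysomnography (PSG) channels:
ECG, pulse-oximetry SaO2, nasal airflow, and abdominal/thoracic respiratory
effort, each annotated with one apnea (A) / normal (N) label per minute.
The pipeline has three stages:

1. **Feature extraction** — 87 named features per one-minute epoch
   (62 ECG, 4 SaO2, 9 airflow, 6 abdominal, 6 thoracic).
2. **Filter selection** — for every patient with both labels, each feature
   is tested A-vs-N with a one-way ANOVA and a Wilcoxon rank-sum test; a
   *positive pair* is ANOVA p < 0.05 together with rank-sum rejection at
   α = 0.05. λ(feature) counts positive pairs across the ν contributing
   patients; features with λ ≥ 1 are kept and stratified into classes
   A (λ = ν) through E (λ = ν − 4).
3. **SVM evaluation** — cumulative class sets A, AB, …, ABCDE are scored
   with soft-margin SVMs over a kernel grid (linear; polynomial
   (x·y + 1)^d, d ∈ {2,3,4}; RBF exp(−‖x−y‖²/2σ²), σ ∈ {1,5,25}; each with
   R ∈ {0.2, 1, 10}) under stratified 10-fold cross-validation.  Within
   every training fold the majority class is randomly under-sampled to the
   minority count and features are z-scored with training-fold statistics;
   the test fold is untouched, so no balancing or scaling information
   leaks.  The hill-climb keeps the class set with the greatest mean
   accuracy across grid configurations; exact ties go to the smaller
   accuracy spread across configurations, then to the earlier (smaller)
   set.

No multiple-testing correction is applied in stage 2: λ is a ranking
device, not an inference procedure.

## Signal conditioning

* ECG and effort channels: order-3 Butterworth band-pass 0.05–40 Hz,
  applied forward-backward (zero phase) so that feature timing cannot
  shift relative to the annotations.  The analytic consequence is that the
  effective magnitude response is |H|².
* Airflow: 10-s running-median baseline correction, order-3 low-pass at
  3 Hz, then block-mean downsampling to 1 Hz.
* SaO2: one-pass artifact repair — any sample differing from its
  predecessor by more than 8 percentage points (judged on the raw trace)
  is replaced by the median of the record's first 10 s — then block-mean
  downsampling to 1 Hz.
* Running medians are centered with shrunken edge windows.  On long
  100 Hz channels the pipeline estimates the baseline on a 10 Hz
  block-mean copy and interpolates it back; the baseline is band-limited
  far below 1 Hz, so this is numerically indistinguishable from the exact
  per-sample median (tested) and an order of magnitude cheaper.
* Block-mean downsampling doubles as the anti-alias step; no second
  filter design is involved.

## ECG features

Beats are found with a Pan-Tompkins detector (5–15 Hz band-pass,
five-point derivative, squaring, 150 ms moving-window integration,
adaptive signal/noise thresholds with a 200 ms refractory period), refined
to the local ECG maximum within ±50 ms.  Epochs with fewer than 10 beats
carry no usable HRV information and are dropped (logged).  RR intervals
outside 300–2000 ms or deviating more than 20 % from the median of the
centered 5-interval neighbourhood are linearly interpolated — standard
HRV artifact bounds.  NN50 is directional: successor exceeding predecessor
by more than 50 ms.  The ECG-derived respiration (EDR) surrogate is the
R-wave area: the integral of the ECG over the 120 ms window centered on
each R peak.

Wavelet statistics use periodized orthogonal decompositions (sym3 to
level 7 for the raw epoch; db4 toward level 9 for the per-beat EDR series,
falling back to the deepest feasible level for short series).  Shannon
entropy is computed on the normalized squared-coefficient distribution
with 0·ln 0 := 0.  The wavelet spectral density of the RR and R-amplitude
series is total detail energy per sample at the deepest feasible level.
Periodization keeps Parseval exact on dyadic lengths; non-dyadic epoch
lengths involve boundary padding with relative energy drift around 1e-4.

RR and EDR series are resampled to an even 4 Hz grid (cubic spline over
beat times) before Welch estimation.  Reported spectral bands that extend
above the record's Nyquist frequency (10–20 Hz and 80–100 Hz at a 100 Hz
record) are remapped as fractions of a 200 Hz-rate Nyquist, e.g.
[80, 100] Hz → [0.8, 1.0] × Nyquist = [40, 50] Hz; bands fully below
Nyquist stay literal.  The five spectral-shape descriptors (flatness,
centroid, spread, decrease, slope) follow the standard audio-descriptor
definitions and are computed on the Welch PSD of the filtered ECG epoch.

Recurrence quantification embeds the RR series with m = 3, τ = 1,
ε = 0.2 × std(rr), minimum line length 2, main diagonal excluded; DET and
LAM are the fractions of recurrent points on diagonal/vertical lines, and
the longest-diagonal statistic is reported under the name V_MAX.  QRS
analysis stacks the 120 ms windows: PCA eigenvalues of the beat
covariance, and RBF kernel PCA with bandwidth set to the median pairwise
beat distance on the double-centered kernel matrix.

## SaO2, airflow and effort features

RES4 counts rapid resaturations: second *t* starts an event when the trace
rises by more than 4 percentage points within 10 s, contiguous qualifying
start-seconds merge into one event, and the trailing 10 s of the previous
minute are available as context so events straddling the minute boundary
are not lost (the first minute has none).  The rise threshold is absolute
percentage points, consistent with the 8-point artifact rule.  SD1 is the
Poincaré short axis, algebraically √(var(Δs)/2).  The SaO2 band feature is
the mean of an AR(5) Yule-Walker spectrum over 0.016–0.05 Hz on a
512-point grid.

Airflow uses Welch with 5-sample Hamming segments and 2-sample overlap
(the fractional 2.5-sample overlap floored to an integer) and a level-3
db3 decomposition with signed coefficient means.  Effort channels report
amplitude statistics plus the mean AR(5) Yule-Walker PSD over the
(remapped) 80–100 Hz band, averaged over 40-sample analysis segments; the
AR order matches the SaO2 estimator.  The Levinson-Durbin recursion is
vectorised across segments (150 segments per minute would otherwise
dominate runtime) and is cross-checked against statsmodels in the tests.

## Synthetic cohorts

The generator emulates a labeled overnight cohort: per-minute labels drawn
with a configurable apnea fraction, ECG built from Gaussian-bump QRS
templates at sequentially drawn beat times, 0.25 Hz airflow/effort
sinusoids, and SaO2 near 97 %.  Apnea minutes impose four signatures with
nominal effect sizes:

* cyclic RR variation — a 30-s-period sinusoid of amplitude
  `rr_effect` = 100 ms **plus** proportionally elevated beat-to-beat
  variability (noise sd 25 ms × (1 + rr_effect/100), i.e. doubled at
  nominal).  The smooth cycle alone cannot move NN50: its per-beat
  increments are ≈ 2π·100/30 ≈ 21 ms, far below the 50 ms threshold; the
  elevated short-term variation models the vagally mediated beat-to-beat
  component of cyclic heart-rate variation and is what makes NN50, SDSD
  and RMSSD discriminative.  Both terms vanish when `rr_effect` = 0, so
  zero-effect cohorts are label-exchangeable.
* a desaturation ramp of `desat_depth` = 6 points over ~20 s with
  recovery inside `desat_recovery_s` = 8 s, tripping the 4-point/10-s
  resaturation rule;
* an airflow amplitude collapse of `airflow_drop` = 0.9 for a random
  10–30 s span;
* abdominal amplitude × `abdo_gain` = 2 for the minute.

Events are minute-aligned — one event per apnea minute — which keeps
labels unambiguous; real recordings have events straddling minute
boundaries, sub-minute hypopneas, movement artifacts and non-stationary
baselines, none of which the generator models.  Passing tests therefore
demonstrate that the pipeline recovers planted physiology of the stated
kind and magnitude, not clinical performance.  The ECG is a template
train, not a dynamical heart model; it is sufficient for every
implemented extractor.  Per-patient streams are spawned independently from
the master seed by patient index, so record content is order-invariant.

## Problem sizes and numerical choices

The end-to-end tests use 5-patient × 200-minute cohorts over 20 seeds —
1000 epochs per cohort, apnea fraction 0.4 — which gives the per-patient
tests ~80 vs ~120 samples, comfortably inside the asymptotic rank-sum
branch, while a full 21-configuration grid × 10-fold hill-climb stays
tractable on one CPU.  The rank-sum test switches to the exact null only
for min(n₁, n₂) ≤ 10 without ties.  Degenerate inputs are defined
explicitly: zero within-group variance with unequal means → ANOVA p = 0;
all values identical → p = 1; constant traces give zero AR spectra and
zero variability features; all-zero spectra make shape features missing
(NaN); NaNs entering the SVM stage are zero-filled after standardization
decisions are made per training fold.

## Known limitations

* The WFDB reader/writer covers the subset this package produces
  (format-16 signals, one shared sampling rate, A/N annotation streams);
  it is round-trip tested against the CSV dialect, not against third-party
  binaries.
* Reported 80–100 Hz band features at a 100 Hz sampling rate exist only
  through the Nyquist remapping convention described above (config-visible
  in `apneapsg.spectral`).
* The per-minute design cannot represent events straddling minute
  boundaries except through the RES4 context window.
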