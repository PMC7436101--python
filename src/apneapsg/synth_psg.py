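"""Synthetic labeled PSG cohorts.

The generator emulates the per-minute structure of an annotated overnight
polysomnogram and the four physiological signatures the feature stack
targets:

* cyclic RR-interval variation during apnea minutes (sinusoidal modulation
  of the beat-to-beat interval with a 30 s period),
* SaO2 desaturation with a rapid (> 4 percentage points within 10 s)
  resaturation,
* a >= 10 s collapse of the airflow envelope,
* elevated abdominal excursion while the airway is closed.

Normal minutes are stationary: RR ~ N(1000, 25^2) ms, ECG built from
Gaussian-bump QRS templates at the beat times, airflow and effort channels
0.25 Hz sinusoids, SaO2 near 97%.  Events are minute-aligned (one event per
apnea minute), which keeps labels unambiguous; real recordings have events
straddling minute boundaries.

All randomness flows from ``SynthParams.seed``; each patient's stream is
spawned independently by index, so record content depends only on
(seed, patient_index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_psg import CHANNEL_NAMES, SignalRecord


@dataclass
class SynthParams:
    """Cohort-level generation parameters (nominal study conditions)."""

    n_patients: int = 5
    minutes_per_patient: int = 200
    apnea_fraction: float = 0.4
    rr_effect: float = 100.0      # ms amplitude of cyclic RR modulation
    desat_depth: float = 6.0      # percentage points
    desat_recovery_s: float = 8.0  # <= 10 s so the resaturation trips RES4
    airflow_drop: float = 0.9     # fractional amplitude reduction
    abdo_gain: float = 2.0        # apnea-minute abdominal amplitude multiplier
    fs: float = 100.0
    noise_sd: dict[str, float] = field(default_factory=lambda: {
        "ECG": 0.03, "SaO2": 0.2, "AIRFLOW": 0.05,
        "ABDOMINAL": 0.05, "THORACIC": 0.05,
    })
    seed: int = 0
    #: patient indices forced to all-normal labels (the "healthy control"
    #: records that contribute no test pair to the selection stage)
    normal_patient_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.apnea_fraction <= 1.0:
            raise ValueError("apnea_fraction must be in [0, 1]")
        if not 0.0 <= self.airflow_drop <= 1.0:
            raise ValueError("airflow_drop must be in [0, 1]")
        if self.abdo_gain < 1.0:
            raise ValueError("abdo_gain must be >= 1")
        if self.desat_recovery_s > 10.0:
            raise ValueError("desat_recovery_s must be <= 10 s to model rapid resaturation")


BEAT_SIGMA_S = 0.012  # Gaussian QRS template width
BREATH_HZ = 0.25


def _gaussian_bumps(beat_times: np.ndarray, amps: np.ndarray, n: int, fs: float
                    ) -> np.ndarray:
    """Sum of Gaussian QRS templates at the given beat times."""
    x = np.zeros(n)
    half = int(round(4 * BEAT_SIGMA_S * fs))
    support = np.arange(-half, half + 1)
    for t, a in zip(beat_times, amps):
        c = int(round(t * fs))
        idx = support + c
        ok = (idx >= 0) & (idx < n)
        x[idx[ok]] += a * np.exp(-((idx[ok] - t * fs) ** 2) / (2 * (BEAT_SIGMA_S * fs) ** 2))
    return x


def generate_record(p: SynthParams, patient_index: int) -> SignalRecord:
    """One patient's synthetic five-channel record with per-minute labels."""
    ss = np.random.SeedSequence(p.seed, spawn_key=(patient_index,))
    rng = np.random.default_rng(ss)
    fs = p.fs
    minutes = p.minutes_per_patient
    n = int(round(minutes * 60 * fs))
    t = np.arange(n) / fs

    if patient_index in p.normal_patient_indices:
        labels = np.array(["N"] * minutes, dtype=object)
    else:
        labels = np.where(rng.random(minutes) < p.apnea_fraction, "A", "N").astype(object)
    is_apnea = labels == "A"

    # ---- beat times: sequential RR draws, modulated inside apnea minutes.
    # Apnea minutes superpose the slow cyclic variation (period 30 s,
    # amplitude rr_effect) and proportionally elevated beat-to-beat
    # variability (vagally mediated short-term variation); both scale with
    # rr_effect and vanish when it is zero.
    beat_times = []
    rr_amps = []
    tick = 0.0
    while tick < minutes * 60:
        m = min(int(tick // 60), minutes - 1)
        if is_apnea[m]:
            sd = 25.0 * (1.0 + p.rr_effect / 100.0)
            rr = 1000.0 + rng.normal(0.0, sd)
            rr += p.rr_effect * np.sin(2 * np.pi * (tick % 60) / 30.0)
        else:
            rr = 1000.0 + rng.normal(0.0, 25.0)
        rr = max(400.0, rr)
        tick += rr / 1000.0
        if tick < minutes * 60:
            beat_times.append(tick)
            rr_amps.append(1.0 + rng.normal(0.0, 0.05))
    beat_times = np.asarray(beat_times)
    rr_amps = np.asarray(rr_amps)
    ecg = _gaussian_bumps(beat_times, rr_amps, n, fs)
    ecg += rng.normal(0.0, p.noise_sd["ECG"], n)

    # ---- SaO2: 97% baseline; apnea minutes get a desaturation ramp with a
    # rapid recovery well inside the 4%/10 s restoration rule
    spo2 = np.full(n, 97.0)
    spo2 += rng.normal(0.0, p.noise_sd["SaO2"], n)
    n_min = int(round(60 * fs))
    for m in np.flatnonzero(is_apnea):
        base = m * n_min
        fall_a, fall_b = int(18 * fs), int(38 * fs)      # ~20 s decline
        rec_b = fall_b + int(p.desat_recovery_s * fs)     # fast resaturation
        seg = np.zeros(n_min)
        seg[fall_a:fall_b] = np.linspace(0.0, -p.desat_depth, fall_b - fall_a)
        seg[fall_b:rec_b] = np.linspace(-p.desat_depth, 0.0, rec_b - fall_b)
        spo2[base : base + n_min] += seg
    np.clip(spo2, 0.0, 100.0, out=spo2)

    # ---- airflow: breathing sinusoid; apnea minutes lose amplitude for a
    # 10-30 s span
    phase_air = rng.uniform(0, 2 * np.pi)
    envelope = np.ones(n)
    for m in np.flatnonzero(is_apnea):
        span = rng.uniform(10.0, 30.0)
        start = rng.uniform(5.0, 55.0 - min(span, 50.0))
        a = m * n_min + int(start * fs)
        b = min((m + 1) * n_min, a + int(span * fs))
        envelope[a:b] = 1.0 - p.airflow_drop
    airflow = envelope * np.sin(2 * np.pi * BREATH_HZ * t + phase_air)
    airflow += rng.normal(0.0, p.noise_sd["AIRFLOW"], n)

    # ---- effort channels: abdominal amplitude grows during apnea minutes,
    # thoracic stays at baseline
    phase_ab = rng.uniform(0, 2 * np.pi)
    gain = np.ones(n)
    for m in np.flatnonzero(is_apnea):
        gain[m * n_min : (m + 1) * n_min] = p.abdo_gain
    abdo = gain * np.sin(2 * np.pi * BREATH_HZ * t + phase_ab)
    abdo += rng.normal(0.0, p.noise_sd["ABDOMINAL"], n)
    thor = np.sin(2 * np.pi * BREATH_HZ * t + rng.uniform(0, 2 * np.pi))
    thor += rng.normal(0.0, p.noise_sd["THORACIC"], n)

    channels = {"ECG": ecg, "SaO2": spo2, "AIRFLOW": airflow,
                "ABDOMINAL": abdo, "THORACIC": thor}
    return SignalRecord(f"synth{patient_index:02d}", channels,
                        {c: fs for c in CHANNEL_NAMES}, labels)


def generate_cohort(p: SynthParams) -> list[SignalRecord]:
    """Independent records for every patient in the cohort."""
    return [generate_record(p, i) for i in range(p.n_patients)]
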