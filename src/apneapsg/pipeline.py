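"""Record-to-feature-table pipeline.

Conditioning per channel (applied once to the whole record, then sliced
into minutes):

* ECG: zero-phase 0.05-40 Hz Butterworth band-pass (the 0.05 Hz edge also
  removes baseline wander).
* SaO2: artifact repair (jumps > 8 percentage points replaced by the
  initial 10-s median), then block-mean downsampling to 1 Hz.
* Airflow: 10-s running-median baseline correction, 3 Hz low-pass,
  block-mean downsampling to 1 Hz.
* Effort (abdominal, thoracic): 10-s running-median baseline correction,
  0.05-40 Hz band-pass.

Each annotated minute then yields one row of the 87-column feature table;
minutes whose ECG has fewer than 10 detectable beats are dropped (logged).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import features_airflow, features_ecg, features_effort, features_spo2, registry
from .io_psg import SignalRecord
from .preprocess import (AIRFLOW_LOWPASS, ECG_BANDPASS, EFFORT_BANDPASS,
                         baseline_correct, butter_filter, downsample_1hz,
                         repair_spo2)

log = logging.getLogger(__name__)

META_COLUMNS = ("record_id", "minute_index", "label")

#: baseline estimation rate for long high-rate channels (see preprocess)
BASELINE_APPROX_FS = 10.0


def conditioned_channels(record: SignalRecord) -> dict[str, np.ndarray]:
    """Apply per-channel conditioning to the full record."""
    fs = record.fs
    ecg = butter_filter(record.channels["ECG"], fs["ECG"], ECG_BANDPASS)
    spo2 = downsample_1hz(repair_spo2(record.channels["SaO2"], fs["SaO2"]), fs["SaO2"])
    air = baseline_correct(record.channels["AIRFLOW"], fs["AIRFLOW"],
                           approx_fs=BASELINE_APPROX_FS)
    air = downsample_1hz(butter_filter(air, fs["AIRFLOW"], AIRFLOW_LOWPASS), fs["AIRFLOW"])
    abdo = butter_filter(
        baseline_correct(record.channels["ABDOMINAL"], fs["ABDOMINAL"],
                         approx_fs=BASELINE_APPROX_FS),
        fs["ABDOMINAL"], EFFORT_BANDPASS)
    thor = butter_filter(
        baseline_correct(record.channels["THORACIC"], fs["THORACIC"],
                         approx_fs=BASELINE_APPROX_FS),
        fs["THORACIC"], EFFORT_BANDPASS)
    return {"ECG": ecg, "SaO2": spo2, "AIRFLOW": air,
            "ABDOMINAL": abdo, "THORACIC": thor}


def extract_features(record: SignalRecord) -> pd.DataFrame:
    """Per-minute feature table: record_id, minute_index, label + 87 columns."""
    cond = conditioned_channels(record)
    fs_ecg = record.fs["ECG"]
    fs_eff = record.fs["ABDOMINAL"]
    n_ecg = int(round(60 * fs_ecg))
    n_eff = int(round(60 * fs_eff))
    rows: list[dict[str, float | int | str]] = []
    dropped = 0
    for m in range(record.duration_min):
        ecg_w = cond["ECG"][m * n_ecg : (m + 1) * n_ecg]
        ecg_vals = features_ecg.extract(ecg_w, fs_ecg)
        if ecg_vals is None:
            dropped += 1
            continue
        spo2_w = cond["SaO2"][m * 60 : (m + 1) * 60]
        context = cond["SaO2"][max(0, m * 60 - 10) : m * 60] if m > 0 else None
        air_w = cond["AIRFLOW"][m * 60 : (m + 1) * 60]
        abdo_w = cond["ABDOMINAL"][m * n_eff : (m + 1) * n_eff]
        thor_w = cond["THORACIC"][m * n_eff : (m + 1) * n_eff]

        row: dict[str, float | int | str] = {
            "record_id": record.record_id,
            "minute_index": m,
            "label": str(record.labels[m]),
        }
        for name, vals in (
            ("ecg", ecg_vals),
            ("spo2", features_spo2.spo2_features(spo2_w, context)),
            ("airflow", features_airflow.airflow_features(air_w)),
            ("abdo", features_effort.abdominal_features(abdo_w, fs_eff)),
            ("thor", features_effort.thoracic_features(thor_w, record.fs["THORACIC"])),
        ):
            for key, value in vals.items():
                row[f"{name}:{key}"] = value
        rows.append(row)
    if dropped:
        log.info("record %s: dropped %d of %d minutes (insufficient beats)",
                 record.record_id, dropped, record.duration_min)
    frame = pd.DataFrame(rows)
    columns = list(META_COLUMNS) + list(registry.FEATURE_COLUMNS)
    if frame.empty:
        return pd.DataFrame(columns=columns)
    missing = set(columns) - set(frame.columns)
    if missing:
        raise RuntimeError(f"extractor did not report features: {sorted(missing)}")
    return frame[columns]


def extract_cohort(records: list[SignalRecord]) -> pd.DataFrame:
    """Concatenated feature table for a list of records."""
    tables = [extract_features(r) for r in records]
    return pd.concat(tables, ignore_index=True)
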