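"""Record containers and readers/writers for multi-channel PSG data.

A :class:`SignalRecord` holds five channels (ECG, SaO2, airflow, abdominal
and thoracic effort) plus one apnea/normal label per minute.  Records can be
read from WFDB-style files (header + 16-bit signal file + apnea annotation
stream) or from a plain CSV dialect with a sidecar label file, and are
sliced into aligned one-minute :class:`EpochView` windows.

Windows are 0-based and half-open: epoch ``m`` covers samples
``[m*60*fs, (m+1)*60*fs)`` of each channel.  Samples beyond the last
annotated minute are discarded (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from . import wfdb_io

log = logging.getLogger(__name__)

#: canonical channel names, in storage order
CHANNEL_NAMES = ("ECG", "SaO2", "AIRFLOW", "ABDOMINAL", "THORACIC")

#: CSV column per channel
_CSV_COLUMNS = {"ECG": "ecg", "SaO2": "spo2", "AIRFLOW": "airflow",
                "ABDOMINAL": "abdo", "THORACIC": "thor"}

#: case-insensitive aliases mapping WFDB signal descriptions to channels
DEFAULT_ALIASES: dict[str, str] = {
    "ecg": "ECG",
    "sao2": "SaO2",
    "spo2": "SaO2",
    "airflow": "AIRFLOW",
    "flow": "AIRFLOW",
    "resp a": "ABDOMINAL",
    "abdo": "ABDOMINAL",
    "abdomen": "ABDOMINAL",
    "abdominal": "ABDOMINAL",
    "resp c": "THORACIC",
    "thor": "THORACIC",
    "thorax": "THORACIC",
    "chest": "THORACIC",
    "thoracic": "THORACIC",
}


class FormatError(ValueError):
    """Input files that exist but do not match the expected layout."""


@dataclass(frozen=True)
class ChannelSpec:
    name: str
    fs: float

    def __post_init__(self) -> None:
        if self.name not in CHANNEL_NAMES:
            raise ValueError(f"unknown channel name {self.name!r}")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")


@dataclass
class SignalRecord:
    """One subject's channels, sampling rates, and per-minute labels."""

    record_id: str
    channels: dict[str, np.ndarray]
    fs: dict[str, float]
    labels: np.ndarray  # array of 'A'/'N', one per minute
    duration_min: int = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(self.labels) - {"A", "N"}
        if bad:
            raise FormatError(f"record {self.record_id}: labels outside A/N: {sorted(bad)}")
        self.duration_min = len(self.labels)
        for name, x in self.channels.items():
            if name not in CHANNEL_NAMES:
                raise FormatError(f"record {self.record_id}: unknown channel {name!r}")
            need = int(round(self.duration_min * 60 * self.fs[name]))
            if len(x) < need:
                raise FormatError(
                    f"record {self.record_id}: channel {name} has {len(x)} samples, "
                    f"needs {need} for {self.duration_min} annotated minutes"
                )
            if len(x) > need:
                log.info(
                    "record %s: truncating channel %s from %d to %d samples "
                    "(%d annotated minutes)",
                    self.record_id, name, len(x), need, self.duration_min,
                )
                self.channels[name] = np.asarray(x[:need], dtype=float)
            else:
                self.channels[name] = np.asarray(x, dtype=float)


@dataclass(frozen=True)
class EpochView:
    """One aligned one-minute window across all channels."""

    record_id: str
    minute_index: int
    windows: Mapping[str, np.ndarray]
    label: str


def epochs(record: SignalRecord) -> Iterator[EpochView]:
    """Yield the record's one-minute epochs in order (a disjoint partition)."""
    for m in range(record.duration_min):
        windows = {}
        for name, x in record.channels.items():
            n = int(round(60 * record.fs[name]))
            windows[name] = x[m * n : (m + 1) * n]
        yield EpochView(record.record_id, m, windows, str(record.labels[m]))


# ---------------------------------------------------------------------------
# CSV dialect: <record_id>.csv with columns time_s, ecg, spo2, airflow,
# abdo, thor (one shared sampling rate) + <record_id>.labels, one A/N per line.
# ---------------------------------------------------------------------------

def write_csv_record(record: SignalRecord, directory: Path) -> tuple[Path, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rates = {record.fs[c] for c in CHANNEL_NAMES}
    if len(rates) != 1:
        raise FormatError("CSV dialect requires a single shared sampling rate")
    fs = rates.pop()
    n = min(len(record.channels[c]) for c in CHANNEL_NAMES)
    frame = pd.DataFrame({"time_s": np.arange(n) / fs})
    for name in CHANNEL_NAMES:
        frame[_CSV_COLUMNS[name]] = record.channels[name][:n]
    csv_path = directory / f"{record.record_id}.csv"
    lab_path = directory / f"{record.record_id}.labels"
    frame.to_csv(csv_path, index=False, float_format="%.6f")
    lab_path.write_text("\n".join(record.labels) + "\n")
    return csv_path, lab_path


def read_csv_record(path: Path, record_id: str) -> SignalRecord:
    """Read the CSV dialect from directory ``path``."""
    path = Path(path)
    csv_path = path / f"{record_id}.csv"
    lab_path = path / f"{record_id}.labels"
    if not csv_path.exists():
        raise FileNotFoundError(f"missing CSV signal file: {csv_path}")
    if not lab_path.exists():
        raise FileNotFoundError(f"missing label file: {lab_path}")
    try:
        frame = pd.read_csv(csv_path)
    except pd.errors.ParserError as exc:
        raise FormatError(f"ragged CSV {csv_path}: {exc}") from exc
    expected = {"time_s", *_CSV_COLUMNS.values()}
    if set(frame.columns) != expected:
        raise FormatError(
            f"{csv_path}: expected columns {sorted(expected)}, found {sorted(frame.columns)}"
        )
    if frame.isna().any().any():
        row = int(frame.isna().any(axis=1).idxmax())
        raise FormatError(f"{csv_path}: missing value in data row {row}")
    dt = np.diff(frame["time_s"].to_numpy())
    fs = 1.0 / float(np.median(dt))
    labels = [ln.strip() for ln in lab_path.read_text().splitlines() if ln.strip()]
    n_minutes = len(labels)
    need = int(round(n_minutes * 60 * fs))
    if len(frame) < need:
        raise FormatError(
            f"{lab_path}: {n_minutes} labels but only "
            f"{len(frame) / (60 * fs):.2f} minutes of samples"
        )
    channels = {name: frame[_CSV_COLUMNS[name]].to_numpy(float) for name in CHANNEL_NAMES}
    return SignalRecord(record_id, channels, {c: fs for c in CHANNEL_NAMES},
                        np.asarray(labels, dtype=object))


# ---------------------------------------------------------------------------
# WFDB-style records
# ---------------------------------------------------------------------------

def write_wfdb_record(record: SignalRecord, directory: Path,
                      gain: float | None = None) -> None:
    """``gain`` counts/unit; by default chosen per channel to span int16."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rates = {record.fs[c] for c in CHANNEL_NAMES}
    if len(rates) != 1:
        raise FormatError("format-16 writer requires a single shared sampling rate")
    fs = rates.pop()
    sig = np.column_stack([record.channels[c] for c in CHANNEL_NAMES])
    if gain is None:
        peaks = np.maximum(np.abs(sig).max(axis=0), 1e-6)
        gains = 32000.0 / peaks
    else:
        gains = np.full(sig.shape[1], float(gain))
    wfdb_io.write_header(directory / f"{record.record_id}.hea", record.record_id,
                         fs, sig.shape[0], list(CHANNEL_NAMES), gains)
    wfdb_io.write_signals(directory / f"{record.record_id}.dat", sig, gains)
    wfdb_io.write_apnea_annotations(directory / f"{record.record_id}.apn",
                                    list(record.labels), fs)


def read_wfdb_record(
    path: Path, record_id: str, aliases: Mapping[str, str] | None = None
) -> SignalRecord:
    """Read a WFDB-style record (``.hea`` + ``.dat`` + ``.apn``)."""
    path = Path(path)
    aliases = dict(DEFAULT_ALIASES if aliases is None else aliases)
    rid, fs, n_samples, descriptions, gains = wfdb_io.read_header(path / f"{record_id}.hea")
    if len(descriptions) != len(CHANNEL_NAMES):
        raise FormatError(
            f"record {record_id}: expected {len(CHANNEL_NAMES)} channels, "
            f"header lists {len(descriptions)}: {descriptions}"
        )
    mapping = {}
    for idx, desc in enumerate(descriptions):
        key = desc.strip().lower()
        if key not in aliases:
            raise FormatError(f"record {record_id}: unrecognised signal description {desc!r}")
        mapping[aliases[key]] = idx
    missing = set(CHANNEL_NAMES) - set(mapping)
    if missing:
        raise FormatError(f"record {record_id}: channels not found: {sorted(missing)}; "
                          f"header lists {descriptions}")
    signals = wfdb_io.read_signals(path / f"{record_id}.dat", len(descriptions), gains)
    labels = wfdb_io.read_apnea_annotations(path / f"{record_id}.apn")
    channels = {name: signals[:, mapping[name]] for name in CHANNEL_NAMES}
    return SignalRecord(record_id, channels, {c: fs for c in CHANNEL_NAMES},
                        np.asarray(labels, dtype=object))
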