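"""Minimal reader/writer for WFDB-style records (header + format-16 signal
file + per-minute apnea annotation file).

Supports exactly the subset this package needs: a single ``.dat`` file
holding all signals interleaved as 16-bit little-endian two's-complement
integers, a plain-text ``.hea`` header, and an annotation stream with one
label per minute ('A' apnea / 'N' normal) encoded in the MIT annotation
word format (10-bit time delta + 6-bit code, SKIP pseudo-annotations for
deltas over 1023 samples).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

#: MIT annotation codes used by per-minute apnea annotation streams
CODE_NORMAL = 1  # rendered 'N'
CODE_APNEA = 8  # rendered 'A'
CODE_SKIP = 59
CODE_END = 0


class WfdbFormatError(ValueError):
    """Malformed header, signal, or annotation content."""


def write_header(
    path: Path,
    record_id: str,
    fs: float,
    n_samples: int,
    descriptions: list[str],
    gains: "np.ndarray | list[float] | float" = 200.0,
) -> None:
    gains = np.broadcast_to(np.asarray(gains, dtype=float), (len(descriptions),))
    lines = [f"{record_id} {len(descriptions)} {fs:g} {n_samples}"]
    for desc, gain in zip(descriptions, gains):
        lines.append(f"{record_id}.dat 16 {gain:g} 16 0 0 0 0 {desc}")
    path.write_text("\n".join(lines) + "\n")


def read_header(path: Path) -> tuple[str, float, int, list[str], list[float]]:
    """Return (record_id, fs, n_samples, descriptions, gains)."""
    if not path.exists():
        raise FileNotFoundError(f"missing WFDB header file: {path}")
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    if len(head) < 4:
        raise WfdbFormatError(f"bad header line in {path}: {lines[0]!r}")
    record_id, n_sig, fs, n_samples = head[0], int(head[1]), float(head[2]), int(head[3])
    descriptions: list[str] = []
    gains: list[float] = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split(None, 8)
        if len(parts) < 9 or parts[1] != "16":
            raise WfdbFormatError(f"unsupported signal line in {path}: {ln!r}")
        gains.append(float(parts[2].split("(")[0].split("/")[0]))
        descriptions.append(parts[8])
    if len(descriptions) != n_sig:
        raise WfdbFormatError(f"header {path} declares {n_sig} signals, found {len(descriptions)}")
    return record_id, fs, n_samples, descriptions, gains


def write_signals(path: Path, signals: np.ndarray,
                  gains: "np.ndarray | list[float] | float" = 200.0) -> None:
    """``signals``: (n_samples, n_sig) float array, stored as int16 counts."""
    gains = np.broadcast_to(np.asarray(gains, dtype=float), (signals.shape[1],))
    counts = np.clip(np.round(signals * gains[None, :]), -32768, 32767).astype("<i2")
    path.write_bytes(counts.tobytes())


def read_signals(path: Path, n_sig: int, gains: list[float]) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"missing WFDB signal file: {path}")
    raw = np.frombuffer(path.read_bytes(), dtype="<i2")
    if raw.size % n_sig:
        raise WfdbFormatError(f"signal file {path} length not a multiple of {n_sig} channels")
    counts = raw.reshape(-1, n_sig).astype(float)
    return counts / np.asarray(gains)[None, :]


def write_apnea_annotations(path: Path, labels: list[str], fs: float) -> None:
    """One annotation per minute at sample ``m * 60 * fs``."""
    out = bytearray()
    prev = 0
    for m, lab in enumerate(labels):
        t = int(round(m * 60 * fs))
        delta = t - prev
        prev = t
        if delta > 1023:
            out += struct.pack("<H", CODE_SKIP << 10)
            out += struct.pack("<H", (delta >> 16) & 0xFFFF)
            out += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        code = CODE_APNEA if lab == "A" else CODE_NORMAL
        out += struct.pack("<H", (code << 10) | delta)
    out += struct.pack("<H", 0)  # end of stream
    path.write_bytes(bytes(out))


def read_apnea_annotations(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"missing apnea annotation file: {path}")
    buf = path.read_bytes()
    labels: list[str] = []
    i = 0
    while i + 1 < len(buf):
        (word,) = struct.unpack_from("<H", buf, i)
        i += 2
        code, delta = word >> 10, word & 0x3FF
        if code == CODE_END and delta == 0:
            break
        if code == CODE_SKIP:
            if i + 3 >= len(buf):
                raise WfdbFormatError(f"truncated SKIP annotation in {path}")
            hi, lo = struct.unpack_from("<HH", buf, i)
            i += 4
            continue
        if code == CODE_APNEA:
            labels.append("A")
        elif code == CODE_NORMAL:
            labels.append("N")
        else:
            raise WfdbFormatError(
                f"annotation code {code} in {path} is outside the A/N apnea alphabet"
            )
    return labels
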