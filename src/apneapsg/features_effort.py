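"""Respiratory-effort features: abdominal Nos. 76-81 and thoracic Nos. 82-87.

During obstructive apneas the airway is closed while the diaphragm keeps
working, so abdominal excursion grows relative to normal breathing; the
amplitude statistics of the 60-s effort epochs carry that signature.  Both
channels also report the mean Yule-Walker AR(5) PSD over the published
80-100 Hz band (remapped to the same fraction of the record's Nyquist, see
:mod:`apneapsg.spectral`), averaged over 40-sample analysis segments.
"""

from __future__ import annotations

import numpy as np
import pywt

from .spectral import ar_band_mean, remap_band

AR_ORDER = 5
AR_SEGMENT_LEN = 40


def _effort_band_mean(x: np.ndarray, fs: float) -> float:
    lo, hi = remap_band(80.0, 100.0, fs)
    return ar_band_mean(x, fs, lo, hi, order=AR_ORDER, segment_len=AR_SEGMENT_LEN)


def abdominal_features(x: np.ndarray, fs: float) -> dict[str, float]:
    """sum_abs, std_abs, mean, AR band mean, and db2 depth-2 detail means."""
    x = np.asarray(x, dtype=float)
    coeffs = pywt.wavedec(x, "db2", level=2, mode="periodization")
    _, d2, d1 = coeffs
    return {
        "sum_abs": float(np.abs(x).sum()),
        "std_abs": float(np.std(np.abs(x), ddof=1)) if len(x) > 1 else 0.0,
        "mean": float(np.mean(x)),
        "mean_PSD_80/100_": _effort_band_mean(x, fs),
        "mean_D1": float(np.mean(d1)),
        "mean_D2": float(np.mean(d2)),
    }


def thoracic_features(x: np.ndarray, fs: float) -> dict[str, float]:
    """Plain moments/order statistics of the epoch plus the AR band mean."""
    x = np.asarray(x, dtype=float)
    return {
        "sum": float(np.sum(x)),
        "std": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        "med": float(np.median(x)),
        "mean": float(np.mean(x)),
        "var": float(np.var(x, ddof=1)) if len(x) > 1 else 0.0,
        "mean_PSD_80/100_": _effort_band_mean(x, fs),
    }
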