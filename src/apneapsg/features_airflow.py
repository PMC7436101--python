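"""Airflow features (registry Nos. 67-75) for 1 Hz epochs.

Obstructive events collapse the airflow envelope for 10 s or more, shifting
power from the normal breathing band toward very low frequencies.  The
features are simple moments of the conditioned 1 Hz epoch, Welch band means
over 0-0.1 Hz and 0.4-0.5 Hz (5-sample Hamming segments, 2-sample overlap),
and the signed means of a level-3 Daubechies-3 decomposition.
"""

from __future__ import annotations

import numpy as np
import pywt

from .spectral import band_mean, welch_psd

WELCH_NPERSEG = 5
WELCH_NOVERLAP = 2  # the fractional 2.5-sample overlap floored to an integer


def airflow_features(a: np.ndarray) -> dict[str, float]:
    """The nine airflow features of one conditioned 1 Hz epoch."""
    a = np.asarray(a, dtype=float)
    f, p = welch_psd(a, fs=1.0, nperseg=min(WELCH_NPERSEG, len(a)),
                     noverlap=WELCH_NOVERLAP if len(a) > WELCH_NPERSEG else None,
                     window="hamming")
    wav = pywt.Wavelet("db3")
    level = min(3, max(1, pywt.dwt_max_level(len(a), wav.dec_len)))
    coeffs = pywt.wavedec(a, wav, level=level, mode="periodization")
    details_deep_first = coeffs[1:]
    n_det = len(details_deep_first)
    out = {
        "mean": float(np.mean(a)),
        "med": float(np.median(a)),
        "std": float(np.std(a, ddof=1)) if len(a) > 1 else 0.0,
        "mean_PSD_0/0.1_": band_mean(f, p, 0.0, 0.1),
        "mean_PSD_0.4/0.5_": band_mean(f, p, 0.4, 0.5),
    }
    for i in range(3):
        c = details_deep_first[n_det - 1 - i] if i < n_det else None
        out[f"mean_D{i + 1}"] = float(np.mean(c)) if c is not None else float("nan")
    out["mean_A3"] = float(np.mean(coeffs[0]))
    return out
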