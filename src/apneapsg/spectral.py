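"""Shared spectral estimation helpers.

Welch periodograms come from :func:`scipy.signal.welch`.  Autoregressive
(Yule-Walker) spectra are computed by a small vectorised Levinson-Durbin
recursion so that many short analysis segments can be fitted in one call
(the effort channels average AR spectra over 150 segments per minute, which
makes a per-segment Python loop the dominant cost otherwise).  The
vectorised recursion is cross-checked against statsmodels in the test
suite.

Band conventions: reported heart-rate and respiration bands that extend
above the record's Nyquist frequency (e.g. an 80-100 Hz band on a 100 Hz
record) are remapped as fractions of a 200 Hz-rate Nyquist, i.e.
[80, 100] Hz -> [0.8, 1.0] x Nyquist.  Bands fully below Nyquist are kept
literal.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

log = logging.getLogger(__name__)

#: nominal acquisition rate whose Nyquist the published band edges refer to
BAND_REFERENCE_RATE = 200.0


def remap_band(lo: float, hi: float, fs: float,
               reference_rate: float = BAND_REFERENCE_RATE) -> tuple[float, float]:
    """Map a band that exceeds Nyquist to the same fraction of actual Nyquist."""
    nyq = fs / 2.0
    if hi <= nyq:
        return lo, hi
    ref_nyq = reference_rate / 2.0
    lo2, hi2 = lo / ref_nyq * nyq, hi / ref_nyq * nyq
    log.debug("band [%g, %g] Hz above Nyquist %g; remapped to [%g, %g] Hz",
              lo, hi, nyq, lo2, hi2)
    return lo2, hi2


def band_mean(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Mean PSD over grid points inside [lo, hi] (inclusive)."""
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        return float("nan")
    return float(np.mean(psd[mask]))


def band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Integrated PSD (trapezoidal) over [lo, hi]."""
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def welch_psd(x: np.ndarray, fs: float, nperseg: int | None = None,
              noverlap: int | None = None, window: str = "hann"
              ) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    if nperseg is None:
        nperseg = min(len(x), 256)
    nperseg = min(nperseg, len(x))
    return signal.welch(x, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap)


# ---------------------------------------------------------------------------
# Yule-Walker autoregressive spectra
# ---------------------------------------------------------------------------

def yule_walker_batch(segments: np.ndarray, order: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Fit AR(order) models to each row of ``segments`` (demeaned per row).

    Returns ``(rho, sigma2)`` with ``rho`` of shape (n_seg, order) such that
    ``x_t = sum_k rho[k] x_{t-k} + e_t`` and ``sigma2`` the innovation
    variance, using biased autocovariances (the classic Yule-Walker/MLE
    normalisation).  Degenerate (constant) rows get rho = 0, sigma2 = 0.
    """
    x = np.atleast_2d(np.asarray(segments, dtype=float))
    n_seg, m = x.shape
    if m <= order:
        raise ValueError(f"segments of length {m} too short for AR({order})")
    x = x - x.mean(axis=1, keepdims=True)
    # biased autocovariances r_0..r_order
    r = np.empty((n_seg, order + 1))
    for k in range(order + 1):
        r[:, k] = np.einsum("ij,ij->i", x[:, : m - k], x[:, k:]) / m
    ok = r[:, 0] > 0
    rho = np.zeros((n_seg, order))
    sigma2 = np.zeros(n_seg)
    if ok.any():
        rr = r[ok]
        a = np.zeros((ok.sum(), order))
        e = rr[:, 0].copy()
        for i in range(order):
            acc = rr[:, i + 1].copy()
            for j in range(i):
                acc -= a[:, j] * rr[:, i - j]
            k_ref = acc / e
            a_new = a.copy()
            a_new[:, i] = k_ref
            for j in range(i):
                a_new[:, j] = a[:, j] - k_ref * a[:, i - 1 - j]
            a = a_new
            e = e * (1.0 - k_ref**2)
        rho[ok] = a
        sigma2[ok] = e
    return rho, sigma2


def ar_psd(rho: np.ndarray, sigma2: np.ndarray, fs: float, n_freq: int = 512
           ) -> tuple[np.ndarray, np.ndarray]:
    """One-sided AR PSD on an ``n_freq``-point grid from 0 to Nyquist.

    Accepts a single model (1-D rho) or a batch (2-D); batches return the
    PSD averaged across models.
    """
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    sigma2 = np.atleast_1d(np.asarray(sigma2, dtype=float))
    order = rho.shape[1]
    freqs = np.linspace(0.0, fs / 2.0, n_freq)
    w = 2 * np.pi * freqs / fs  # rad/sample
    # A(w) = 1 - sum_k rho_k e^{-i w k}
    expo = np.exp(-1j * np.outer(np.arange(1, order + 1), w))  # (order, n_freq)
    a_of_w = 1.0 - rho @ expo  # (n_seg, n_freq)
    denom = np.abs(a_of_w) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        psd = 2.0 * sigma2[:, None] / (fs * denom)
    psd[~np.isfinite(psd)] = 0.0
    return freqs, psd.mean(axis=0)


def ar_band_mean(x: np.ndarray, fs: float, lo: float, hi: float,
                 order: int = 5, segment_len: int | None = None,
                 n_freq: int = 512) -> float:
    """Mean Yule-Walker AR PSD over [lo, hi] Hz.

    With ``segment_len``, the signal is cut into non-overlapping segments of
    that length, one AR model per segment, and the PSDs are averaged.
    """
    x = np.asarray(x, dtype=float)
    if segment_len is None or segment_len >= len(x):
        segments = x[None, :]
    else:
        n_seg = len(x) // segment_len
        segments = x[: n_seg * segment_len].reshape(n_seg, segment_len)
    rho, sigma2 = yule_walker_batch(segments, order)
    if not np.any(sigma2 > 0):
        log.debug("degenerate (constant) input for AR spectrum; band mean = 0")
        return 0.0
    freqs, psd = ar_psd(rho, sigma2, fs, n_freq)
    return band_mean(freqs, psd, lo, hi)
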