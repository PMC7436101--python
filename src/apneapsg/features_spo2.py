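"""Oxygen-saturation features (registry Nos. 63-66) for 1 Hz epochs.

Apnea terminations produce a characteristic rapid resaturation: SaO2 falls
during the obstruction and recovers by several percentage points within
seconds of the arousal.  RES4 counts such rapid-restoration events (a rise
of more than 4 percentage points within 10 s); the remaining features are
the epoch median, the mean AR(5) Yule-Walker PSD over the 0.016-0.05 Hz
desaturation band, and the Poincare short-axis SD1.
"""

from __future__ import annotations

import logging

import numpy as np

from .spectral import ar_band_mean

log = logging.getLogger(__name__)

RES4_RISE = 4.0  # percentage points
RES4_HORIZON_S = 10
CONTEXT_S = 10  # trailing seconds of the previous minute


def res4_count(s: np.ndarray, context: np.ndarray | None = None,
               rise: float = RES4_RISE, horizon: int = RES4_HORIZON_S) -> int:
    """Number of rapid-restoration events in a 1 Hz epoch.

    Second ``t`` qualifies as an event start when ``s[t+d] - s[t] > rise``
    for some ``d <= horizon`` with the restoration completing inside the
    epoch; contiguous qualifying start-seconds are merged into one event.
    ``context`` (the trailing seconds of the previous minute) lets events
    whose fall straddles the minute boundary still be caught.
    """
    s = np.asarray(s, dtype=float)
    n_ctx = 0
    if context is not None and len(context):
        ctx = np.asarray(context, dtype=float)[-CONTEXT_S:]
        n_ctx = len(ctx)
        s = np.concatenate([ctx, s])
    qualifies = np.zeros(len(s), dtype=bool)
    for t in range(len(s) - 1):
        upper = min(len(s), t + horizon + 1)
        lo = max(t + 1, n_ctx)  # restoration must land inside the epoch
        if lo < upper and np.max(s[lo:upper]) - s[t] > rise:
            qualifies[t] = True
    padded = np.concatenate(([False], qualifies, [False]))
    starts = np.flatnonzero(np.diff(padded.astype(int)) == 1)
    return int(len(starts))


def sd1(s: np.ndarray) -> float:
    """Poincare short-axis: sqrt(var(successive differences) / 2)."""
    d = np.diff(np.asarray(s, dtype=float))
    if len(d) < 2:
        return 0.0
    return float(np.sqrt(np.var(d, ddof=1) / 2.0))


def spo2_features(s: np.ndarray, context: np.ndarray | None = None) -> dict[str, float]:
    """The four SaO2 features of one repaired, 1 Hz epoch."""
    s = np.asarray(s, dtype=float)
    mean_psd = ar_band_mean(s - s.mean(), fs=1.0, lo=0.016, hi=0.05, order=5)
    return {
        "med": float(np.median(s)),
        "RES4": float(res4_count(s, context)),
        "mean_PSD_0.016/0.05_": mean_psd,
        "SD_1_": sd1(s),
    }
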