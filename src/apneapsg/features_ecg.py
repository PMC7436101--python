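"""ECG-derived features (registry Nos. 1-62) for one-minute epochs.

Covers the full heart-rate-variability stack used for per-minute apnea
scoring: Pan-Tompkins beat detection on the filtered ECG, physiological RR
correction, an R-wave-area ECG-derived-respiration (EDR) surrogate,
time-domain HRV statistics, Daubechies/Symlet wavelet sub-band statistics,
Welch power-spectral features of the RR/EDR series and the raw ECG,
audio-style spectral-shape descriptors, recurrence quantification of the RR
series, serial correlation coefficients, and (kernel) PCA of the stacked
QRS complexes.

Conventions: sample (n-1) variance/std everywhere; kurtosis is the
non-excess Pearson moment ratio; NN50 is directional (successor exceeds
predecessor by more than 50 ms).  Epochs with fewer than 10 detected beats
are unusable for HRV work and are flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import interpolate, signal, stats

from .preprocess import FilterSpec, butter_filter
from .spectral import band_mean, band_power, remap_band, welch_psd

log = logging.getLogger(__name__)

MIN_BEATS = 10  # below this an epoch carries no usable HRV information

# RR physiological band and local-median deviation tolerance
RR_MIN_MS, RR_MAX_MS = 300.0, 2000.0
RR_MEDIAN_TOL = 0.20

QRS_WINDOW_S = 0.120  # symmetric window around each R peak

# recurrence analysis parameters
RQA_DIM, RQA_DELAY, RQA_EPS_FACTOR, RQA_LMIN = 3, 1, 0.2, 2


@dataclass
class BeatSeries:
    """Detected R peaks within one epoch."""

    r_times: np.ndarray  # seconds from epoch start, strictly increasing
    r_amps: np.ndarray

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        self.r_amps = np.asarray(self.r_amps, dtype=float)
        if len(self.r_times) != len(self.r_amps):
            raise ValueError("r_times and r_amps must have equal length")
        if np.any(np.diff(self.r_times) <= 0):
            raise ValueError("r_times must be strictly increasing")

    @property
    def usable(self) -> bool:
        return len(self.r_times) >= MIN_BEATS


# ---------------------------------------------------------------------------
# beat detection (Pan-Tompkins)
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: np.ndarray, fs: float) -> BeatSeries:
    """Pan-Tompkins QRS detection on a filtered, baseline-corrected epoch.

    Stages: 5-15 Hz bandpass, five-point derivative, squaring, 150 ms
    moving-window integration, adaptive signal/noise threshold with a
    200 ms refractory period; detected peaks are refined to the local
    maximum of the input ECG within +-50 ms.
    """
    ecg = np.asarray(ecg, dtype=float)
    n = len(ecg)
    bp = butter_filter(ecg, fs, FilterSpec("bandpass", 2, (5.0, 15.0)))
    deriv = np.convolve(bp, np.array([1, 2, 0, -2, -1]) * fs / 8.0, mode="same")
    sq = deriv**2
    w = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(sq, np.ones(w) / w, mode="same")

    refractory = int(round(0.200 * fs))
    cand, _ = signal.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        return BeatSeries(np.empty(0), np.empty(0))

    head = mwi[: min(n, int(2 * fs))]
    spki = 0.875 * float(head.max())
    npki = 0.5 * float(head.mean())
    if spki <= 0:
        return BeatSeries(np.empty(0), np.empty(0))

    accepted: list[int] = []
    for p in cand:
        h = mwi[p]
        thr = npki + 0.25 * (spki - npki)
        if h > thr:
            accepted.append(p)
            spki = 0.125 * h + 0.875 * spki
        else:
            npki = 0.125 * h + 0.875 * npki

    # refine to the local ECG maximum within +-50 ms
    half = int(round(0.050 * fs))
    refined: list[int] = []
    for p in accepted:
        a, b = max(0, p - half), min(n, p + half + 1)
        refined.append(a + int(np.argmax(ecg[a:b])))
    # enforce refractory on refined positions, keeping the taller peak
    final: list[int] = []
    for idx in sorted(set(refined)):
        if final and idx - final[-1] < refractory:
            if ecg[idx] > ecg[final[-1]]:
                final[-1] = idx
        else:
            final.append(idx)
    peaks = np.asarray(final, dtype=int)
    series = BeatSeries(peaks / fs, ecg[peaks])
    if not series.usable:
        log.debug("epoch flagged unusable: %d beats detected", len(peaks))
    return series


def raw_rr_ms(beats: BeatSeries) -> np.ndarray:
    return np.diff(beats.r_times) * 1000.0


def correct_rr(raw_rr: np.ndarray) -> np.ndarray:
    """Replace non-physiological RR intervals by linear interpolation.

    Intervals outside [300, 2000] ms or deviating more than 20% from the
    median of the centered 5-interval neighbourhood are interpolated from
    the nearest valid neighbours.
    """
    rr = np.asarray(raw_rr, dtype=float)
    if len(rr) < 3:
        log.debug("fewer than 3 RR intervals; returned uncorrected")
        return rr.copy()
    local_med = np.array([
        np.median(rr[max(0, i - 2): i + 3]) for i in range(len(rr))
    ])
    bad = (rr < RR_MIN_MS) | (rr > RR_MAX_MS) | (
        np.abs(rr - local_med) > RR_MEDIAN_TOL * local_med
    )
    if bad.all():
        return np.clip(local_med, RR_MIN_MS, RR_MAX_MS)
    if bad.any():
        idx = np.arange(len(rr))
        rr = rr.copy()
        rr[bad] = np.interp(idx[bad], idx[~bad], rr[~bad])
        log.debug("RR correction replaced %d of %d intervals", int(bad.sum()), len(rr))
    return np.clip(rr, RR_MIN_MS, RR_MAX_MS)


# ---------------------------------------------------------------------------
# EDR and QRS matrix
# ---------------------------------------------------------------------------

def qrs_matrix(ecg: np.ndarray, beats: BeatSeries, fs: float) -> np.ndarray:
    """Stack the 120 ms window centered on each R peak (rows = beats).

    Windows truncated by the epoch edge are zero-padded.
    """
    ecg = np.asarray(ecg, dtype=float)
    cols = int(round(QRS_WINDOW_S * fs))
    half = cols // 2
    out = np.zeros((len(beats.r_times), cols))
    for i, t in enumerate(beats.r_times):
        c = int(round(t * fs))
        a, b = c - half, c - half + cols
        src_a, src_b = max(0, a), min(len(ecg), b)
        out[i, src_a - a : src_a - a + (src_b - src_a)] = ecg[src_a:src_b]
    return out


def derive_edr(ecg: np.ndarray, beats: BeatSeries, fs: float) -> np.ndarray:
    """R-wave-area EDR surrogate: per beat, the integral of the ECG over the
    120 ms QRS window (sum x dt)."""
    q = qrs_matrix(ecg, beats, fs)
    return q.sum(axis=1) / fs


# ---------------------------------------------------------------------------
# time-domain features (Nos. 1-11)
# ---------------------------------------------------------------------------

def _std(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def ecg_time_features(beats: BeatSeries, rr: np.ndarray, edr: np.ndarray,
                      ecg: np.ndarray) -> dict[str, float]:
    d_amp = np.diff(beats.r_amps)
    d_rr = np.diff(rr)
    first = rr[beats.r_times[1:] < 30.0]
    second = rr[beats.r_times[1:] >= 30.0]
    mean_edr = float(np.mean(edr)) if len(edr) else 0.0
    if mean_edr == 0.0:
        cv_edr = float("nan")
        log.debug("mean EDR is zero; CV_EDR missing")
    else:
        cv_edr = _std(edr) / mean_edr
    return {
        "RMSSD_R_amp": float(np.sqrt(np.mean(d_amp**2))) if len(d_amp) else 0.0,
        "NN50_RR": float(np.sum(d_rr > 50.0)),
        "SDSD_RR": _std(d_rr),
        "tSD_RR": _std(np.array([_std(first), _std(second)])),
        "std_RR": _std(rr),
        "mean": float(np.mean(ecg)),
        "var": float(np.var(ecg, ddof=1)),
        "kurtosis": float(stats.kurtosis(ecg, fisher=False)),
        "mean_RR": float(np.mean(rr)),
        "CV_EDR": cv_edr,
        "mean_R_amp": float(np.mean(beats.r_amps)),
    }


# ---------------------------------------------------------------------------
# wavelet features (Nos. 12-39)
# ---------------------------------------------------------------------------

def shannon_entropy(coeffs: np.ndarray) -> float:
    """Shannon entropy of the normalised squared-coefficient distribution."""
    e = np.asarray(coeffs, dtype=float) ** 2
    total = e.sum()
    if total <= 0:
        return 0.0
    p = e[e > 0] / total
    return float(-(p * np.log(p)).sum())


def _wavedec(x: np.ndarray, wavelet: str, level: int) -> list[np.ndarray]:
    wav = pywt.Wavelet(wavelet)
    feasible = pywt.dwt_max_level(len(x), wav.dec_len)
    if feasible < level:
        log.debug("series of %d samples supports level %d < requested %d (%s)",
                  len(x), feasible, level, wavelet)
        level = max(1, feasible)
    return pywt.wavedec(np.asarray(x, dtype=float), wav, level=level,
                        mode="periodization")


def wavelet_spectral_density(x: np.ndarray, wavelet: str = "sym3") -> float:
    """Total detail-coefficient energy per input sample, at the deepest
    feasible decomposition level."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return float("nan")
    wav = pywt.Wavelet(wavelet)
    level = max(1, pywt.dwt_max_level(len(x), wav.dec_len))
    coeffs = pywt.wavedec(x, wav, level=level, mode="periodization")
    detail_energy = sum(float((c**2).sum()) for c in coeffs[1:])
    return detail_energy / len(x)


def ecg_wavelet_features(ecg: np.ndarray, edr: np.ndarray, rr: np.ndarray,
                         r_amps: np.ndarray) -> dict[str, float]:
    out: dict[str, float] = {}
    # EDR: db4, level 9 requested (short series fall back to deepest level)
    if len(edr) >= 8:
        ce = _wavedec(edr, "db4", 9)
        details = ce[1:]  # deepest first
        out["var_EDR_D9"] = float(np.var(details[0], ddof=1)) if len(details[0]) > 1 else 0.0
        d2 = details[-2] if len(details) >= 2 else None
        out["var_EDR_D2"] = (float(np.var(d2, ddof=1))
                             if d2 is not None and len(d2) > 1 else float("nan"))
    else:
        out["var_EDR_D9"] = out["var_EDR_D2"] = float("nan")
    # raw ECG: sym3, level 7; bands ordered D1..D7, A7
    cc = _wavedec(ecg, "sym3", 7)
    approx, details_deep_first = cc[0], cc[1:]
    n_det = len(details_deep_first)
    bands = {f"D{i + 1}": details_deep_first[n_det - 1 - i] for i in range(n_det)}
    bands["A7"] = approx
    for i in range(n_det, 7):
        bands[f"D{i + 1}"] = np.empty(0)
    for name in [f"D{i}" for i in range(1, 8)] + ["A7"]:
        c = bands[name]
        if len(c) == 0:
            out[f"entropy_{name}"] = float("nan")
            out[f"mean_{name}"] = float("nan")
            out[f"var_{name}"] = float("nan")
        else:
            out[f"entropy_{name}"] = shannon_entropy(c)
            out[f"mean_{name}"] = float(np.mean(c))
            out[f"var_{name}"] = float(np.var(c, ddof=1)) if len(c) > 1 else 0.0
    out["WSD_RR"] = wavelet_spectral_density(rr)
    out["WSD_R_amp"] = wavelet_spectral_density(r_amps)
    return out


# ---------------------------------------------------------------------------
# PSD features (Nos. 40-44) and spectral shape (Nos. 45-49)
# ---------------------------------------------------------------------------

RESAMPLE_FS = 4.0  # even grid for beat-indexed series before Welch


def _resample_beat_series(values: np.ndarray, times: np.ndarray,
                          fs_out: float = RESAMPLE_FS) -> np.ndarray:
    """Cubic interpolation of a beat-indexed series onto an even grid."""
    if len(values) < 4:
        return np.empty(0)
    grid = np.arange(times[0], times[-1], 1.0 / fs_out)
    spline = interpolate.CubicSpline(times, values)
    return spline(grid)


def ecg_psd_features(rr: np.ndarray, rr_times: np.ndarray, edr: np.ndarray,
                     edr_times: np.ndarray, ecg: np.ndarray, fs: float,
                     ecg_psd: tuple[np.ndarray, np.ndarray] | None = None
                     ) -> dict[str, float]:
    out = {k: float("nan") for k in
           ("max_PSD_0.03/0.5_", "mean_PSD_10/20_", "mean_PSD_80/100_",
            "var_EDR_0.03/0.4_", "var_RR_0.03/0.4_")}
    rr_even = _resample_beat_series(rr, rr_times)
    if len(rr_even) >= 8:
        f, p = welch_psd(rr_even, RESAMPLE_FS, nperseg=min(len(rr_even), 128))
        mask = (f >= 0.03) & (f <= 0.5)
        if mask.any():
            out["max_PSD_0.03/0.5_"] = float(f[mask][np.argmax(p[mask])])
        out["var_RR_0.03/0.4_"] = band_power(f, p, 0.03, 0.4)
    edr_even = _resample_beat_series(edr, edr_times)
    if len(edr_even) >= 8:
        f, p = welch_psd(edr_even, RESAMPLE_FS, nperseg=min(len(edr_even), 128))
        out["var_EDR_0.03/0.4_"] = band_power(f, p, 0.03, 0.4)
    if ecg_psd is None:
        ecg_psd = welch_psd(ecg, fs, nperseg=min(len(ecg), 256))
    f, p = ecg_psd
    out["mean_PSD_10/20_"] = band_mean(f, p, *remap_band(10.0, 20.0, fs))
    out["mean_PSD_80/100_"] = band_mean(f, p, *remap_band(80.0, 100.0, fs))
    return out


def spectral_shape(freqs: np.ndarray, powers: np.ndarray) -> dict[str, float]:
    """Flatness, centroid, spread, decrease and slope of a one-sided PSD."""
    f = np.asarray(freqs, dtype=float)
    p = np.asarray(powers, dtype=float)
    names = ("spectral flatness", "spectral centroid", "spectral spread",
             "spectral decrease", "spectral slope")
    total = p.sum()
    if len(p) < 2 or total <= 0:
        log.debug("degenerate spectrum; shape features missing")
        return {k: float("nan") for k in names}
    with np.errstate(divide="ignore"):
        logp = np.where(p > 0, np.log(p), -np.inf)
    geo = np.exp(logp.mean()) if np.isfinite(logp).all() else 0.0
    centroid = float((f * p).sum() / total)
    spread = float(np.sqrt(((f - centroid) ** 2 * p).sum() / total))
    k = np.arange(2, len(p) + 1)
    tail = p[1:]
    decrease = float(((tail - p[0]) / (k - 1)).sum() / tail.sum()) if tail.sum() > 0 else 0.0
    slope = float(np.polyfit(f, p, 1)[0])
    return {
        "spectral flatness": float(geo / p.mean()),
        "spectral centroid": centroid,
        "spectral spread": spread,
        "spectral decrease": decrease,
        "spectral slope": slope,
    }


def ecg_spectral_shape(ecg: np.ndarray, fs: float) -> dict[str, float]:
    f, p = welch_psd(ecg, fs, nperseg=min(len(ecg), 256))
    return spectral_shape(f, p)


# ---------------------------------------------------------------------------
# recurrence quantification (Nos. 50-52)
# ---------------------------------------------------------------------------

def rqa_features(rr: np.ndarray, dim: int = RQA_DIM, delay: int = RQA_DELAY,
                 eps_factor: float = RQA_EPS_FACTOR, l_min: int = RQA_LMIN
                 ) -> dict[str, float]:
    """DET, LAM and longest diagonal line of the RR recurrence plot.

    Time-delay embedding (m=3, tau=1); a pair recurs when its Euclidean
    distance is within eps = 0.2 x std(rr).  The main diagonal is excluded.
    """
    rr = np.asarray(rr, dtype=float)
    n_emb = len(rr) - (dim - 1) * delay
    if n_emb < 2:
        return {"V_MAX": float("nan"), "DET": float("nan"), "LAM": float("nan")}
    emb = np.column_stack([rr[i * delay : i * delay + n_emb] for i in range(dim)])
    d2 = ((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1)
    sd = np.std(rr, ddof=1)
    eps = eps_factor * sd if sd > 0 else np.finfo(float).tiny
    rec = d2 <= eps**2
    np.fill_diagonal(rec, False)
    total = int(rec.sum())
    if total == 0:
        return {"V_MAX": 0.0, "DET": 0.0, "LAM": 0.0}

    def _line_stats(mat: np.ndarray, diagonals: bool) -> tuple[int, int]:
        on_lines = 0
        longest = 0
        if diagonals:
            runs_iter = (np.diagonal(mat, off) for off in range(-(n_emb - 1), n_emb) if off != 0)
        else:
            runs_iter = (mat[:, j] for j in range(n_emb))
        for line in runs_iter:
            arr = np.asarray(line)
            if not arr.any():
                continue
            # lengths of True runs
            padded = np.concatenate(([False], arr, [False]))
            edges = np.flatnonzero(np.diff(padded.astype(int)))
            lengths = edges[1::2] - edges[0::2]
            on_lines += int(lengths[lengths >= l_min].sum())
            longest = max(longest, int(lengths.max()))
        return on_lines, longest

    diag_on, v_max = _line_stats(rec, diagonals=True)
    vert_on, _ = _line_stats(rec, diagonals=False)
    return {
        "V_MAX": float(v_max),
        "DET": diag_on / total,
        "LAM": vert_on / total,
    }


# ---------------------------------------------------------------------------
# serial correlation (Nos. 53-57)
# ---------------------------------------------------------------------------

def serial_correlation(rr: np.ndarray, k: int) -> float:
    """Pearson correlation of the RR series with its lag-k copy."""
    rr = np.asarray(rr, dtype=float)
    if len(rr) <= k + 2:
        return float("nan")
    a, b = rr[:-k], rr[k:]
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# QRS (kernel) PCA (Nos. 58-62)
# ---------------------------------------------------------------------------

def qrs_pca_features(q: np.ndarray) -> dict[str, float]:
    """PCA and RBF kernel-PCA statistics of the stacked QRS windows."""
    q = np.asarray(q, dtype=float)
    n = q.shape[0]
    names = ("std_PCA", "std_kPCA", "max_dia_PCA", "max_dia_kPCA", "RP_2_PC")
    if n < 3:
        return {k: float("nan") for k in names}
    centered = q - q.mean(axis=0, keepdims=True)
    cov = centered.T @ centered / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals[::-1], 0.0, None)
    evecs = evecs[:, ::-1]
    total = evals.sum()
    scores1 = centered @ evecs[:, 0]
    out = {
        "std_PCA": _std(scores1),
        "max_dia_PCA": float(evals[0]),
        "RP_2_PC": float(evals[1] / total) if total > 0 else 0.0,
    }
    # RBF kernel PCA; bandwidth = median pairwise row distance
    d2 = ((q[:, None, :] - q[None, :, :]) ** 2).sum(-1)
    iu = np.triu_indices(n, k=1)
    sigma = float(np.median(np.sqrt(d2[iu])))
    if sigma <= 0:
        out["std_kPCA"] = 0.0
        out["max_dia_kPCA"] = 0.0
        return out
    kmat = np.exp(-d2 / (2 * sigma**2))
    one = np.full((n, n), 1.0 / n)
    kc = kmat - one @ kmat - kmat @ one + one @ kmat @ one
    kevals, kevecs = np.linalg.eigh(kc)
    kevals = np.clip(kevals[::-1], 0.0, None)
    kevecs = kevecs[:, ::-1]
    kscores1 = kevecs[:, 0] * np.sqrt(kevals[0])
    out["std_kPCA"] = _std(kscores1)
    out["max_dia_kPCA"] = float(kevals[0] / n)
    return out


# ---------------------------------------------------------------------------
# full 62-feature extraction for one epoch
# ---------------------------------------------------------------------------

def extract(ecg_epoch: np.ndarray, fs: float) -> dict[str, float] | None:
    """All 62 ECG features for one filtered epoch; None if unusable."""
    beats = detect_r_peaks(ecg_epoch, fs)
    if not beats.usable:
        return None
    rr = correct_rr(raw_rr_ms(beats))
    rr_times = beats.r_times[1:]
    edr = derive_edr(ecg_epoch, beats, fs)
    q = qrs_matrix(ecg_epoch, beats, fs)

    ecg_psd = welch_psd(ecg_epoch, fs, nperseg=min(len(ecg_epoch), 256))
    out: dict[str, float] = {}
    out.update(ecg_time_features(beats, rr, edr, ecg_epoch))
    out.update(ecg_wavelet_features(ecg_epoch, edr, rr, beats.r_amps))
    out.update(ecg_psd_features(rr, rr_times, edr, beats.r_times, ecg_epoch, fs,
                                ecg_psd=ecg_psd))
    out.update(spectral_shape(*ecg_psd))
    out.update(rqa_features(rr))
    for k in range(1, 6):
        out[f"SCrC_{k}_RR"] = serial_correlation(rr, k)
    out.update(qrs_pca_features(q))
    return out
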