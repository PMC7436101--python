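"""ECG feature extractors against closed-form and brute-force oracles."""

import numpy as np
import pytest
import pywt
from scipy import signal

from apneapsg import features_ecg as fe
from apneapsg.preprocess import ECG_BANDPASS, FilterSpec, butter_filter

FS = 100.0


def beat_train(beat_times, fs=FS, seconds=60.0, amps=None, noise=0.0, seed=0):
    """Gaussian-bump QRS template train (ground-truth beat times known)."""
    rng = np.random.default_rng(seed)
    t = np.arange(0, seconds, 1 / fs)
    x = np.zeros_like(t)
    amps = np.ones(len(beat_times)) if amps is None else np.asarray(amps)
    for b, a in zip(beat_times, amps):
        x += a * np.exp(-((t - b) ** 2) / (2 * 0.012**2))
    if noise:
        x += rng.normal(0, noise, len(t))
    return butter_filter(x, fs, ECG_BANDPASS)


class TestDetectRPeaks:
    def test_recovers_known_beat_times(self):
        truth = np.arange(0.5, 60, 1.0)
        beats = fe.detect_r_peaks(beat_train(truth, noise=0.03), FS)
        assert abs(len(beats.r_times) - len(truth)) <= 1
        matched = [np.min(np.abs(truth - t)) for t in beats.r_times]
        assert max(matched) <= 0.050

    def test_flat_line_flagged_unusable(self):
        beats = fe.detect_r_peaks(np.zeros(6000), FS)
        assert not beats.usable

    def test_invariant_to_amplitude_scaling(self):
        truth = np.arange(0.4, 60, 0.9)
        x = beat_train(truth, noise=0.02)
        a = fe.detect_r_peaks(x, FS)
        b = fe.detect_r_peaks(10.0 * x, FS)
        np.testing.assert_array_equal(a.r_times, b.r_times)


class TestCorrectRR:
    def test_clean_series_unchanged(self):
        rr = np.full(20, 1000.0)
        np.testing.assert_array_equal(fe.correct_rr(rr), rr)

    def test_outlier_replaced_by_interpolation(self):
        out = fe.correct_rr(np.array([1000.0, 1000.0, 250.0, 1000.0]))
        np.testing.assert_allclose(out, [1000, 1000, 1000, 1000])

    def test_output_within_physiological_band(self, rng):
        rr = rng.uniform(100, 3000, 200)
        out = fe.correct_rr(rr)
        assert out.min() >= 300.0 and out.max() <= 2000.0

    def test_too_short_returned_unchanged(self):
        rr = np.array([100.0, 5000.0])
        np.testing.assert_array_equal(fe.correct_rr(rr), rr)


class TestEdr:
    def test_identical_beats_give_constant_edr(self):
        # identical templates at known beat positions, no filtering: every
        # 120 ms window is the same, so the EDR is exactly constant
        truth = np.arange(0.5, 60, 1.0)
        t = np.arange(0, 60, 1 / FS)
        x = np.zeros_like(t)
        for b in truth:
            x += np.exp(-((t - b) ** 2) / (2 * 0.012**2))
        beats = fe.BeatSeries(truth, np.ones(len(truth)))
        edr = fe.derive_edr(x, beats, FS)
        assert np.std(edr) / np.mean(edr) == pytest.approx(0.0, abs=1e-9)

    def test_amplitude_modulation_sets_dominant_edr_frequency(self):
        truth = np.arange(0.5, 60, 1.0)
        amps = 1.0 + 0.4 * np.sin(2 * np.pi * 0.3 * truth)
        x = beat_train(truth, amps=amps)
        beats = fe.detect_r_peaks(x, FS)
        edr = fe.derive_edr(x, beats, FS)
        f, p = signal.periodogram(edr - edr.mean(), fs=1.0)
        assert f[np.argmax(p)] == pytest.approx(0.3, abs=0.05)

    def test_linearity_in_ecg_amplitude(self):
        truth = np.arange(0.5, 30, 1.0)
        x = beat_train(truth, seconds=30)
        beats = fe.detect_r_peaks(x, FS)
        np.testing.assert_allclose(fe.derive_edr(2 * x, beats, FS),
                                   2 * fe.derive_edr(x, beats, FS), rtol=1e-12)


class TestTimeFeatures:
    def test_constant_rr_zeroes_variability(self):
        truth = np.arange(0.5, 60, 1.0)
        x = beat_train(truth)
        beats = fe.BeatSeries(truth, np.ones(len(truth)))
        rr = np.full(len(truth) - 1, 1000.0)
        feats = fe.ecg_time_features(beats, rr, np.ones(len(truth)), x)
        assert feats["NN50_RR"] == 0
        assert feats["SDSD_RR"] == 0
        assert feats["std_RR"] == 0
        assert feats["mean_RR"] == 1000.0

    def test_nn50_is_directional(self):
        beats = fe.BeatSeries(np.arange(5.0), np.ones(5))
        rr = np.array([800.0, 860.0, 900.0, 949.0])
        feats = fe.ecg_time_features(beats, rr, np.ones(5), np.zeros(100))
        # brute force: only 800->860 exceeds +50 ms
        assert feats["NN50_RR"] == 1

    def test_kurtosis_uses_pearson_convention(self, rng):
        x = rng.standard_normal(6000)
        beats = fe.BeatSeries(np.arange(10.0) + 0.5, np.ones(10))
        feats = fe.ecg_time_features(beats, np.full(9, 1000.0), np.ones(10), x)
        assert feats["kurtosis"] == pytest.approx(3.0, abs=0.2)


class TestWaveletFeatures:
    @pytest.mark.parametrize("wavelet,level,n", [
        ("sym3", 7, 4096), ("db4", 9, 4096), ("db3", 3, 64), ("db2", 2, 64),
    ])
    def test_parseval_energy_conservation(self, rng, wavelet, level, n):
        # periodized orthogonal DWT conserves energy exactly on dyadic lengths
        x = rng.standard_normal(n)
        coeffs = pywt.wavedec(x, wavelet, level=level, mode="periodization")
        energy = sum(float((c**2).sum()) for c in coeffs)
        assert energy == pytest.approx(float((x**2).sum()), rel=1e-6)

    def test_energy_nearly_conserved_on_epoch_length(self, rng):
        # non-dyadic lengths involve boundary padding; energy drift stays tiny
        x = rng.standard_normal(6000)
        coeffs = pywt.wavedec(x, "sym3", level=7, mode="periodization")
        energy = sum(float((c**2).sum()) for c in coeffs)
        assert energy == pytest.approx(float((x**2).sum()), rel=1e-3)

    def test_entropy_closed_forms(self):
        assert fe.shannon_entropy(np.array([0.0, 3.0, 0.0])) == 0.0
        assert fe.shannon_entropy(np.array([2.0, -2.0])) == pytest.approx(np.log(2))

    def test_constant_ecg_zero_detail_bands(self):
        feats = fe.ecg_wavelet_features(np.full(6000, 2.0), np.ones(60),
                                        np.full(59, 1000.0), np.ones(60))
        for i in range(1, 8):
            assert feats[f"mean_D{i}"] == pytest.approx(0.0, abs=1e-9)
            assert feats[f"var_D{i}"] == pytest.approx(0.0, abs=1e-9)
        assert feats["mean_A7"] != 0.0

    def test_wsd_matches_direct_energy_sum(self, rng):
        x = rng.standard_normal(60)
        coeffs = pywt.wavedec(x, "sym3", level=pywt.dwt_max_level(60, 6),
                              mode="periodization")
        expected = sum(float((c**2).sum()) for c in coeffs[1:]) / 60
        assert fe.wavelet_spectral_density(x) == pytest.approx(expected, rel=1e-12)


class TestPsdFeatures:
    def test_rr_modulation_frequency_located(self):
        times = np.cumsum(np.full(70, 0.9))
        times = times[times < 63]
        rr = 900.0 + 80 * np.sin(2 * np.pi * 0.1 * times)
        feats = fe.ecg_psd_features(rr, times, rr, times, np.zeros(6000), FS)
        assert feats["max_PSD_0.03/0.5_"] == pytest.approx(0.1, abs=0.04)

    def test_white_noise_band_means_comparable(self, rng):
        x = rng.standard_normal(6000)
        feats = fe.ecg_psd_features(np.full(59, 1000.0), np.arange(1, 60.0),
                                    np.ones(60), np.arange(60.0), x, FS)
        lo, hi = feats["mean_PSD_10/20_"], feats["mean_PSD_80/100_"]
        assert lo > 0 and hi > 0
        assert abs(lo - hi) / max(lo, hi) < 0.25

    def test_constant_rr_has_no_band_power(self):
        feats = fe.ecg_psd_features(np.full(59, 1000.0), np.arange(1, 60.0),
                                    np.ones(60), np.arange(60.0), np.zeros(6000), FS)
        assert feats["var_RR_0.03/0.4_"] == pytest.approx(0.0, abs=1e-9)


class TestSpectralShape:
    def test_flat_spectrum_closed_form(self):
        f = np.linspace(0, 10, 11)
        p = np.full(11, 2.0)
        shape = fe.spectral_shape(f, p)
        assert shape["spectral flatness"] == pytest.approx(1.0)
        assert shape["spectral decrease"] == pytest.approx(0.0)
        assert shape["spectral slope"] == pytest.approx(0.0, abs=1e-12)
        assert shape["spectral centroid"] == pytest.approx(f.mean())

    def test_single_line_spectrum(self):
        f = np.array([1.0, 2.0, 3.0])
        p = np.array([0.0, 5.0, 0.0])
        shape = fe.spectral_shape(f, p)
        assert shape["spectral centroid"] == pytest.approx(2.0)
        assert shape["spectral spread"] == pytest.approx(0.0)
        assert shape["spectral flatness"] == pytest.approx(0.0)

    def test_two_bin_hand_computation(self):
        shape = fe.spectral_shape(np.array([1.0, 2.0]), np.array([1.0, 3.0]))
        assert shape["spectral centroid"] == pytest.approx(1.75)
        assert shape["spectral spread"] == pytest.approx(np.sqrt(0.1875))


class TestRqa:
    def test_constant_series_fully_recurrent(self):
        feats = fe.rqa_features(np.full(30, 1000.0))
        n_emb = 30 - (fe.RQA_DIM - 1)  # embedded points
        # every off-diagonal pair recurs; the only recurrent points NOT on a
        # line of length >= 2 are the two corner diagonals (length 1) and,
        # for columns, the two single-cell runs created by the excluded
        # main diagonal -- exact enumeration of the fully recurrent plot
        total = n_emb * n_emb - n_emb
        assert feats["DET"] == pytest.approx((total - 2) / total)
        assert feats["LAM"] == pytest.approx((total - 2) / total)
        assert feats["V_MAX"] == n_emb - 1

    def test_structure_raises_determinism(self, rng):
        dets_noise, dets_sine = [], []
        t = np.arange(200)
        for seed in range(10):
            r = np.random.default_rng(seed)
            dets_noise.append(fe.rqa_features(r.uniform(900, 1100, 200))["DET"])
            sine = 1000 + 80 * np.sin(2 * np.pi * t / 20) + r.normal(0, 10, 200)
            dets_sine.append(fe.rqa_features(sine)["DET"])
        assert np.median(dets_sine) > np.median(dets_noise)

    def test_bounds(self, rng):
        feats = fe.rqa_features(rng.normal(1000, 50, 80))
        assert 0.0 <= feats["DET"] <= 1.0
        assert 0.0 <= feats["LAM"] <= 1.0
        assert feats["V_MAX"] <= 80 - fe.RQA_DIM + 1 - 1


class TestSerialCorrelation:
    def test_periodic_series_perfectly_correlated_at_period(self):
        rr = np.tile([900.0, 1100.0], 30)
        assert fe.serial_correlation(rr, 2) == pytest.approx(1.0)

    def test_iid_noise_uncorrelated(self, rng):
        rr = rng.normal(1000, 50, 1000)
        assert abs(fe.serial_correlation(rr, 1)) < 0.1

    def test_affine_invariance(self, rng):
        rr = rng.normal(1000, 50, 100)
        for k in range(1, 6):
            assert fe.serial_correlation(3.0 * rr + 7.0, k) == pytest.approx(
                fe.serial_correlation(rr, k), rel=1e-9)


class TestQrsPca:
    def test_identical_beats_degenerate_spectrum(self):
        q = np.tile(np.sin(np.linspace(0, np.pi, 12)), (8, 1))
        feats = fe.qrs_pca_features(q)
        assert feats["max_dia_PCA"] == pytest.approx(0.0, abs=1e-12)
        assert feats["RP_2_PC"] == 0.0

    def test_rank_one_construction(self, rng):
        v = np.zeros(12)
        v[3] = 1.0
        a = rng.normal(0, 2.0, 20)
        q = 0.5 + np.outer(a, v)
        feats = fe.qrs_pca_features(q)
        assert feats["RP_2_PC"] == pytest.approx(0.0, abs=1e-12)
        assert feats["max_dia_PCA"] == pytest.approx(np.var(a, ddof=1), rel=1e-9)

    def test_eigenvalue_trace_identity(self, rng):
        q = rng.normal(size=(25, 12))
        centered = q - q.mean(axis=0)
        total_var = float((centered**2).sum()) / (25 - 1)
        cov = centered.T @ centered / 24
        evals = np.linalg.eigvalsh(cov)
        assert evals.sum() == pytest.approx(total_var, rel=1e-9)
        feats = fe.qrs_pca_features(q)
        assert feats["max_dia_PCA"] == pytest.approx(evals.max(), rel=1e-9)


class TestEpochInvariance:
    def test_features_do_not_depend_on_absolute_start_time(self):
        truth = np.arange(0.35, 60, 0.8)
        x = beat_train(truth, noise=0.02, seed=5)
        a = fe.extract(x, FS)
        b = fe.extract(x.copy(), FS)
        for key in a:
            assert a[key] == pytest.approx(b[key], nan_ok=True), key

    def test_all_features_finite_on_nominal_epoch(self, short_record):
        from apneapsg.pipeline import conditioned_channels
        cond = conditioned_channels(short_record)
        feats = fe.extract(cond["ECG"][:6000], FS)
        assert feats is not None
        assert len(feats) == 62
        assert all(np.isfinite(v) for v in feats.values())
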