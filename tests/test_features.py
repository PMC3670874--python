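import numpy as np
import pytest
import pywt

from fscore_elm import (
    FEATURE_NAMES,
    ErpResponse,
    SymmetricMinMaxScaler,
    burg_psd,
    extract_features,
    frequency_features,
    normalizer_apply,
    normalizer_fit,
    time_domain_features,
    wavelet_features,
)
from fscore_elm.features import WaveletConfigError
from fscore_elm.simulate import _hann_bump
from sklearn.exceptions import NotFittedError


def resp(samples, t0=-0.2, fs=500.0):
    return ErpResponse(np.asarray(samples, dtype=float), t0, fs, "A", 1)


class TestTimeDomain:
    def test_unit_raised_cosine(self):
        t = -0.2 + np.arange(500) / 500.0
        x = _hann_bump(t, 1.0, 0.3, 0.3)
        v_max, t_max, r_la, v_min, v_ptp, a_p = time_domain_features(resp(x))
        assert v_max == pytest.approx(1.0)
        assert t_max == pytest.approx(0.3)
        assert r_la == pytest.approx(0.3)
        assert v_min == pytest.approx(0.0)
        assert v_ptp == pytest.approx(1.0)
        assert a_p > 0

    def test_all_zero_conventions(self):
        v_max, t_max, r_la, v_min, v_ptp, a_p = time_domain_features(resp(np.zeros(500)))
        assert (v_max, v_min, v_ptp, a_p, r_la) == (0, 0, 0, 0, 0)

    def test_positive_area_hand_integral(self):
        # +2 uV over a full 1 s window integrates to 2 uV.s
        _, _, _, _, _, a_p = time_domain_features(resp(np.full(500, 2.0), t0=0.0))
        assert a_p == pytest.approx(2.0)

    def test_window_is_post_stimulus_only(self):
        t = -0.2 + np.arange(500) / 500.0
        x = np.where(t < 0, 100.0, 1.0)  # huge pre-stimulus values must not count
        v_max, *_ = time_domain_features(resp(x))
        assert v_max == pytest.approx(1.0)


class TestBurgPsd:
    def test_sinusoid_peak_matches_periodogram_oracle(self):
        from scipy.signal import periodogram

        fs = 500.0
        t = np.arange(2000) / fs
        x = np.sin(2 * np.pi * 5.0 * t)
        freqs, power = burg_psd(x, order=20, n_freq=512, fs=fs)
        bin_width = freqs[1] - freqs[0]
        f_or, p_or = periodogram(x, fs=fs)
        oracle_peak = f_or[np.argmax(p_or)]
        assert abs(freqs[np.argmax(power)] - oracle_peak) <= bin_width
        assert np.all(power >= 0)

    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=4000)
        _, power = burg_psd(x, order=4, n_freq=256, fs=500.0)
        assert power.max() < 10 * np.median(power)

    def test_zero_signal_gives_zero_spectrum(self):
        freqs, power = burg_psd(np.zeros(500), order=20)
        assert freqs.size == 512
        np.testing.assert_array_equal(power, 0.0)

    def test_order_must_be_below_length(self):
        with pytest.raises(ValueError):
            burg_psd(np.ones(10), order=10)


class TestFrequencyFeatures:
    def test_single_bin(self):
        freqs = np.arange(0.0, 126.0)
        power = np.zeros_like(freqs)
        power[3] = 5.0
        f_max, f_mean, a_lf = frequency_features(freqs, power)
        assert (f_max, f_mean) == (3.0, 3.0)
        assert a_lf == pytest.approx(5.0)  # bin width 1 Hz

    def test_two_bin_weighted_mean_and_band(self):
        freqs = np.arange(0.0, 126.0)
        power = np.zeros_like(freqs)
        power[2] = power[6] = 4.0
        f_max, f_mean, a_lf = frequency_features(freqs, power)
        assert f_mean == pytest.approx(4.0)
        assert a_lf == pytest.approx(4.0)  # only the 2 Hz bin is inside 0.1-3.9

    def test_zero_spectrum_convention(self):
        freqs = np.linspace(0, 250, 64)
        assert frequency_features(freqs, np.zeros(64)) == (0.0, 0.0, 0.0)


class TestWaveletFeatures:
    def test_count_matches_cascade_recurrence(self):
        # independent oracle: n_j = floor((n_{j-1} + L - 1) / 2)
        n = 500
        L = pywt.Wavelet("db8").dec_len
        for _ in range(6):
            n = (n + L - 1) // 2
        w = wavelet_features(np.random.default_rng(0).normal(size=500))
        assert w.size == n == 22

    def test_zero_signal_gives_22_zeros(self):
        w = wavelet_features(np.zeros(500))
        assert w.size == 22
        np.testing.assert_array_equal(w, 0.0)

    def test_linearity(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=500)
        np.testing.assert_allclose(
            wavelet_features(3.0 * x), 3.0 * wavelet_features(x), rtol=1e-12
        )

    def test_wrong_combination_reports_count(self):
        with pytest.raises(WaveletConfigError, match=r"\d+"):
            wavelet_features(np.zeros(500), wavelet="db4")


class TestExtractFeatures:
    def test_single_response_row(self):
        t = -0.2 + np.arange(500) / 500.0
        table = extract_features([resp(_hann_bump(t, 8.0, 0.35, 0.3))])
        assert table.shape == (1, 33)
        assert list(table.columns) == ["subject_id", "label", *FEATURE_NAMES]
        assert sum(c.startswith("W_") for c in table.columns) == 22

    def test_empty_input_keeps_header(self):
        table = extract_features([])
        assert len(table) == 0
        assert list(table.columns) == ["subject_id", "label", *FEATURE_NAMES]

    def test_identical_responses_identical_rows(self):
        r = resp(np.sin(np.arange(500) / 20.0))
        table = extract_features([r, r])
        np.testing.assert_array_equal(
            table.iloc[0, 2:].to_numpy(dtype=float), table.iloc[1, 2:].to_numpy(dtype=float)
        )

    def test_ptp_identity_and_class_separation(self, study_table):
        np.testing.assert_allclose(
            study_table.V_ptp, study_table.V_max - study_table.V_min, atol=1e-12
        )
        assert (
            study_table.loc[study_table.label == 1, "V_max"].mean()
            > study_table.loc[study_table.label == -1, "V_max"].mean()
        )


class TestNormalizer:
    def test_training_extremes_map_to_unit_interval(self):
        X = np.array([[0.0], [10.0], [5.0]])
        s = SymmetricMinMaxScaler().fit(X)
        np.testing.assert_allclose(s.transform(X).ravel(), [-1.0, 1.0, 0.0])

    def test_constant_column_maps_to_zero(self):
        X = np.full((3, 1), 5.0)
        np.testing.assert_array_equal(SymmetricMinMaxScaler().fit(X).transform(X), 0.0)

    def test_unseen_values_not_clipped(self):
        s = SymmetricMinMaxScaler().fit(np.array([[0.0], [10.0]]))
        assert s.transform(np.array([[20.0]]))[0, 0] == pytest.approx(3.0)

    def test_apply_before_fit_raises(self):
        with pytest.raises(NotFittedError):
            SymmetricMinMaxScaler().transform(np.zeros((1, 2)))

    def test_table_wrappers_round_trip(self, study_table):
        scaler = normalizer_fit(study_table)
        out = normalizer_apply(scaler, study_table)
        feats = out[[c for c in out.columns if c not in ("subject_id", "label")]]
        assert feats.to_numpy().min() == pytest.approx(-1.0)
        assert feats.to_numpy().max() == pytest.approx(1.0)
        assert (out.label == study_table.label).all()
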