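import numpy as np
import pytest

from aad.containers import EEGRecording
from aad.montages import DRY_LABELS, get_montage
from aad.preprocessing import (RobustScaler, bandpass_eeg, build_lag_matrix,
                               concatenate_part_matrices, extract_envelope,
                               fit_robust_scaler, resample_to_100hz,
                               subsample_channels)


def naive_lag_matrix(eeg: np.ndarray, n_lags: int) -> np.ndarray:
    """Independent double-loop oracle for the design-matrix layout."""
    n_ch, T = eeg.shape
    rows = T - n_lags + 1
    A = np.zeros((rows, n_ch * n_lags))
    for t in range(rows):
        for c in range(n_ch):
            for l in range(n_lags):
                A[t, c * n_lags + l] = eeg[c, t + l]
    return A


class TestResample:
    def test_dc_preserved(self):
        out = resample_to_100hz(np.full(5000, 3.0), 1000.0)
        assert out.size == 500
        assert np.allclose(out[20:-20], 3.0, atol=1e-6)

    def test_sine_amplitude_preserved(self):
        # 10 Hz tone from 300 Hz must match the analytically sampled sine
        t_in = np.arange(3000) / 300.0
        out = resample_to_100hz(np.sin(2 * np.pi * 10 * t_in), 300.0)
        expected = np.sin(2 * np.pi * 10 * np.arange(1000) / 100.0)
        interior = slice(50, -50)
        assert out.size == 1000
        amplitude = np.sqrt(2 * np.mean(out[interior] ** 2))
        assert amplitude == pytest.approx(1.0, rel=0.02)
        assert np.allclose(out[interior], expected[interior], atol=0.02)

    def test_above_nyquist_removed(self):
        t = np.arange(5000) / 1000.0
        out = resample_to_100hz(np.sin(2 * np.pi * 80 * t), 1000.0)
        assert np.sqrt(np.mean(out[25:-25] ** 2)) < 0.05

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError, match="upsampling"):
            resample_to_100hz(np.zeros(100), 50.0)


class TestBandpass:
    def _rec(self, data, fs=100.0):
        labels = [f"ch{i}" for i in range(np.atleast_2d(data).shape[0])]
        return EEGRecording(np.atleast_2d(data), fs, labels)

    def test_dc_removed(self):
        out = bandpass_eeg(self._rec(np.full(2000, 5.0)))
        assert np.abs(out.data[0, 100:-100]).max() < 1e-6 * 5.0

    def test_passband_gain(self):
        t = np.arange(4000) / 100.0
        out = bandpass_eeg(self._rec(np.sin(2 * np.pi * 10 * t)))
        amp = np.abs(out.data[0, 200:-200]).max()
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuation(self):
        t = np.arange(4000) / 100.0
        x = np.sin(2 * np.pi * 45 * t)
        out = bandpass_eeg(self._rec(x))
        ratio = (np.sqrt(np.mean(out.data[0, 200:-200] ** 2))
                 / np.sqrt(np.mean(x[200:-200] ** 2)))
        assert 20 * np.log10(ratio) < -20.0

    def test_invalid_band(self):
        with pytest.raises(ValueError):
            bandpass_eeg(self._rec(np.zeros(1000)), hi=60.0)

    def test_zero_phase(self):
        # a symmetric pulse stays symmetric around its center (no group delay)
        x = np.zeros(2001)
        x[1000] = 1.0
        out = bandpass_eeg(self._rec(x)).data[0]
        assert int(np.abs(out).argmax()) == pytest.approx(1000, abs=1)


class TestEnvelope:
    def test_silence(self):
        env = extract_envelope(np.zeros(16000), 16000.0)
        assert np.allclose(env.values, 0.0)
        assert len(env) == 100

    def test_am_modulator_recovered(self):
        fs = 16000.0
        t = np.arange(int(4 * fs)) / fs
        mod = 0.5 * (1 - np.cos(2 * np.pi * 4 * t))  # 4 Hz raised cosine
        audio = mod * np.sin(2 * np.pi * 1000 * t)
        env = extract_envelope(audio, fs)
        mod100 = mod[:: int(fs // 100)][: len(env)]
        r = np.corrcoef(env.values, mod100)[0, 1]
        assert r > 0.95
        assert env.values.min() >= 0.0

    def test_homogeneity(self, rng):
        audio = rng.standard_normal(16000)
        e1 = extract_envelope(audio, 16000.0).values
        e2 = extract_envelope(2.0 * audio, 16000.0).values
        interior = slice(5, -5)
        assert np.allclose(e2[interior], 2.0 * e1[interior], rtol=0.01,
                           atol=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            extract_envelope(np.array([]), 16000.0)
        with pytest.raises(ValueError):
            extract_envelope(np.zeros(100), 4000.0)
        with pytest.raises(KeyError, match="unknown envelope extractor"):
            extract_envelope(np.zeros(16000), 16000.0, method="nope")


class TestRobustScaler:
    def test_median_subtracted(self):
        s = fit_robust_scaler(np.array([1.0, 2.0, 3.0, 100.0])[:, None])
        assert s.medians[0] == pytest.approx(2.5)
        out = s.transform(np.array([1.0, 2.0, 3.0, 100.0])[:, None])
        assert np.median(out) == pytest.approx(0.0)

    def test_hand_iqr_convention(self):
        # [0, 10]: linear-interpolation percentiles give median 5, IQR 5
        s = fit_robust_scaler(np.array([0.0, 10.0])[:, None])
        assert s.medians[0] == pytest.approx(5.0)
        out = s.transform(np.array([0.0, 10.0])[:, None]).ravel()
        assert np.allclose(out, [-1.0, 1.0])

    def test_train_fold_standardized(self, rng):
        x = rng.standard_normal((500, 3)) * [1.0, 5.0, 0.1] + [0, 3, -2]
        s = fit_robust_scaler(x)
        out = s.transform(x)
        assert np.allclose(np.median(out, axis=0), 0.0, atol=1e-12)
        q25, q75 = np.percentile(out, [25, 75], axis=0)
        assert np.allclose(q75 - q25, 1.0, atol=1e-12)

    def test_inverse_transform(self, rng):
        x = rng.standard_normal((100, 4))
        s = fit_robust_scaler(x)
        assert np.allclose(s.inverse_transform(s.transform(x)), x, atol=1e-10)

    def test_degenerate_feature_named(self):
        x = np.column_stack([np.arange(10.0), np.ones(10)])
        with pytest.raises(ValueError, match=r"\[1\]"):
            fit_robust_scaler(x)


class TestLagMatrix:
    def test_hand_example(self):
        lm = build_lag_matrix(np.array([[0.0, 1, 2, 3, 4]]), n_lags=3)
        assert np.array_equal(lm.A, [[0, 1, 2], [1, 2, 3], [2, 3, 4]])

    def test_shape_64ch(self, rng):
        lm = build_lag_matrix(rng.standard_normal((64, 1000)), n_lags=26)
        assert lm.A.shape == (975, 1664)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_naive_oracle(self, trial):
        r = np.random.default_rng(trial)
        n_ch = int(r.integers(1, 6))
        T = int(r.integers(5, 51))
        n_lags = int(r.integers(1, min(T, 10) + 1))
        eeg = r.standard_normal((n_ch, T))
        lm = build_lag_matrix(eeg, n_lags=n_lags)
        assert np.array_equal(lm.A, naive_lag_matrix(eeg, n_lags))

    def test_target_alignment(self, rng):
        eeg = rng.standard_normal((2, 30))
        target = rng.standard_normal(30)
        lm, t = build_lag_matrix(eeg, n_lags=5, target=target)
        assert t.size == lm.n_rows == 26
        assert np.array_equal(t, target[:26])

    def test_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            build_lag_matrix(np.zeros((2, 10)), n_lags=11)


class TestConcatenate:
    def _pairs(self, rng, n_parts=2, T=40, n_ch=3, n_lags=4):
        out = []
        for _ in range(n_parts):
            eeg = rng.standard_normal((n_ch, T))
            target = rng.standard_normal(T)
            out.append(build_lag_matrix(eeg, n_lags=n_lags, target=target))
        return out

    def test_row_counts(self, rng):
        pairs = self._pairs(rng)
        lm, y = concatenate_part_matrices(pairs)
        assert lm.n_rows == sum(p[0].n_rows for p in pairs)
        assert y.size == lm.n_rows

    def test_rows_preserved(self, rng):
        pairs = self._pairs(rng, n_parts=3)
        lm, _ = concatenate_part_matrices(pairs)
        stacked = {tuple(row) for row in lm.A}
        per_part = {tuple(row) for p in pairs for row in p[0].A}
        assert stacked == per_part

    def test_errors(self, rng):
        with pytest.raises(ValueError, match="no parts"):
            concatenate_part_matrices([])
        a = build_lag_matrix(rng.standard_normal((2, 20)), 3,
                             target=np.zeros(20))
        b = build_lag_matrix(rng.standard_normal((3, 20)), 3,
                             target=np.zeros(20))
        with pytest.raises(ValueError, match="mismatch"):
            concatenate_part_matrices([a, b])


class TestSubsampleChannels:
    def test_wet_to_dry(self, rng):
        labels, positions = get_montage("wet")
        rec = EEGRecording(rng.standard_normal((64, 100)), 100.0,
                           list(labels), positions)
        out = subsample_channels(rec, DRY_LABELS)
        assert out.channel_labels == list(DRY_LABELS)
        assert out.n_channels == 18
        for i, label in enumerate(DRY_LABELS):
            src = rec.channel_labels.index(label)
            assert np.array_equal(out.data[i], rec.data[src])

    def test_identity(self, rng):
        rec = EEGRecording(rng.standard_normal((3, 50)), 100.0,
                           ["a", "b", "c"])
        out = subsample_channels(rec, ["a", "b", "c"])
        assert np.array_equal(out.data, rec.data)

    def test_missing_label_named(self, rng):
        rec = EEGRecording(rng.standard_normal((2, 50)), 100.0, ["a", "b"])
        with pytest.raises(KeyError, match="XX"):
            subsample_channels(rec, ["a", "XX"])
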