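"""Signal conditioning: resampling, band-pass filtering, envelope extraction,
robust scaling, and lagged design matrices.

All decoders operate on EEG and audio envelopes aligned on a common 100-Hz
timeline, band-limited to 2-32 Hz (EEG), robust-scaled per feature with
statistics estimated on training data only.  The design ("lag") matrix ``A``
holds, in each row, a context window of every EEG channel: row ``t`` contains
EEG samples at times ``t .. t+L-1`` so that the envelope sample at time ``t``
is predicted from EEG at and after ``t`` (the neural response follows the
stimulus).  Columns are channel-major: all lags of channel 0, then all lags
of channel 1, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .containers import FS_TARGET, EEGRecording, Envelope

DEFAULT_N_LAGS = 26  #: 26 samples at 100 Hz ~ 250 ms context window


# ---------------------------------------------------------------------------
# resampling and filtering
# ---------------------------------------------------------------------------

def resample_to_100hz(x: np.ndarray, fs_in: float) -> np.ndarray:
    """Resample a signal (last axis = time) to 100 Hz with anti-aliasing.

    Polyphase resampling with a low-pass at the new Nyquist (50 Hz) is
    applied before decimation.  Upsampling is not supported.
    """
    x = np.asarray(x, dtype=float)
    if fs_in < FS_TARGET:
        raise ValueError(
            f"fs_in={fs_in} Hz < 100 Hz: upsampling is not supported"
        )
    n_in = x.shape[-1]
    n_out = int(round(n_in * FS_TARGET / fs_in))
    if fs_in == FS_TARGET:
        return x.copy()
    frac = Fraction(FS_TARGET / fs_in).limit_denominator(1000)
    y = signal.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    # resample_poly returns ceil(n*up/down) samples; pin to round(n*100/fs)
    if y.shape[-1] > n_out:
        y = y[..., :n_out]
    elif y.shape[-1] < n_out:
        pad = n_out - y.shape[-1]
        y = np.concatenate([y, np.repeat(y[..., -1:], pad, axis=-1)], axis=-1)
    return y


def bandpass_eeg(rec: EEGRecording, lo: float = 2.0, hi: float = 32.0,
                 order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass (default 2-32 Hz) per channel.

    Applied forward-backward (sosfiltfilt), so there is no group delay and
    the effective attenuation is doubled relative to a single pass.
    """
    if hi >= rec.fs / 2:
        raise ValueError(
            f"upper edge {hi} Hz must be below Nyquist ({rec.fs / 2} Hz)"
        )
    if rec.fs < 2 * hi:
        raise ValueError("sampling rate too low for requested band")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return rec.copy_with(filtered)


# ---------------------------------------------------------------------------
# envelope extraction (pluggable)
# ---------------------------------------------------------------------------

_ENVELOPE_EXTRACTORS: dict[str, callable] = {}


def register_envelope_extractor(name: str):
    """Decorator registering an alternative envelope extraction algorithm."""

    def deco(fn):
        _ENVELOPE_EXTRACTORS[name] = fn
        return fn

    return deco


@register_envelope_extractor("hilbert")
def _hilbert_envelope(audio: np.ndarray, fs_audio: float) -> np.ndarray:
    """Magnitude of the analytic signal, low-passed at 25 Hz, at 100 Hz."""
    env = np.abs(signal.hilbert(audio))
    sos = signal.butter(4, 25.0, btype="low", fs=fs_audio, output="sos")
    env = signal.sosfiltfilt(sos, env)
    env = resample_to_100hz(env, fs_audio)
    return np.clip(env, 0.0, None)


def extract_envelope(audio: np.ndarray, fs_audio: float, *,
                     talker_id: str = "talker",
                     method: str = "hilbert") -> Envelope:
    """Broadband envelope of a speech waveform at 100 Hz (non-negative)."""
    audio = np.asarray(audio, dtype=float).ravel()
    if audio.size == 0:
        raise ValueError("empty audio")
    if fs_audio < 8000:
        raise ValueError(f"fs_audio={fs_audio} Hz < 8 kHz")
    try:
        fn = _ENVELOPE_EXTRACTORS[method]
    except KeyError:
        raise KeyError(
            f"unknown envelope extractor {method!r}; "
            f"registered: {sorted(_ENVELOPE_EXTRACTORS)}"
        ) from None
    return Envelope(fn(audio, fs_audio), talker_id=talker_id)


# ---------------------------------------------------------------------------
# robust scaling
# ---------------------------------------------------------------------------

@dataclass
class RobustScaler:
    """Per-feature (x - median) / IQR scaling, fitted on training data only.

    IQR is the 75th minus the 25th percentile with linear interpolation.
    A zero IQR is an error: it indicates a degenerate (constant) feature.
    """

    medians: np.ndarray
    iqrs: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x - self.medians) / self.iqrs

    def inverse_transform(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) * self.iqrs + self.medians


def fit_robust_scaler(train_features: np.ndarray) -> RobustScaler:
    """Fit a :class:`RobustScaler` on (n_samples, n_features) training data.

    A 1-D input is treated as a single feature.
    """
    x = np.asarray(train_features, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples to fit a scaler")
    q25, med, q75 = np.percentile(x, [25.0, 50.0, 75.0], axis=0)
    iqr = q75 - q25
    bad = np.flatnonzero(iqr == 0)
    if bad.size:
        raise ValueError(
            f"degenerate feature(s) with zero IQR at index {bad.tolist()}"
        )
    if squeeze:
        return RobustScaler(medians=med[0], iqrs=iqr[0])
    return RobustScaler(medians=med, iqrs=iqr)


def apply_robust_scaler(scaler: RobustScaler, features: np.ndarray) -> np.ndarray:
    return scaler.transform(features)


# ---------------------------------------------------------------------------
# lag matrices
# ---------------------------------------------------------------------------

@dataclass
class LagMatrix:
    """Design matrix of channel-major context windows.

    ``A[t, c * n_lags + l]`` equals EEG channel ``c`` at time ``t + l``.
    Rows requiring samples beyond the part end are dropped, so a part of
    ``T`` samples yields ``T - n_lags + 1`` rows.
    """

    A: np.ndarray
    n_channels: int
    n_lags: int

    def __post_init__(self) -> None:
        if self.A.shape[1] != self.n_channels * self.n_lags:
            raise ValueError("column count != n_channels * n_lags")

    @property
    def n_rows(self) -> int:
        return self.A.shape[0]


def build_lag_matrix(eeg: np.ndarray, n_lags: int = DEFAULT_N_LAGS,
                     target: np.ndarray | None = None):
    """Build the lagged design matrix from (n_channels, T) EEG.

    Returns ``LagMatrix`` or, when ``target`` is given, a tuple
    ``(LagMatrix, target[:T - n_lags + 1])`` with the aligned target slice.
    """
    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    n_ch, T = eeg.shape
    if T < n_lags:
        raise ValueError(
            f"part too short: {T} samples < n_lags={n_lags}"
        )
    # (n_ch, T-L+1, L) -> (T-L+1, n_ch, L) -> channel-major flatten
    win = sliding_window_view(eeg, n_lags, axis=1)
    A = np.ascontiguousarray(win.transpose(1, 0, 2)).reshape(T - n_lags + 1, -1)
    lm = LagMatrix(A=A, n_channels=n_ch, n_lags=n_lags)
    if target is None:
        return lm
    target = np.asarray(target, dtype=float).ravel()
    if target.size != T:
        raise ValueError("target length must equal EEG sample count")
    return lm, target[: T - n_lags + 1]


def concatenate_part_matrices(pairs) -> tuple[LagMatrix, np.ndarray]:
    """Stack per-part (LagMatrix, target) pairs row-wise, in part order.

    Matrices are built per part *before* concatenation so no row straddles
    a part boundary.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no parts to concatenate")
    first = pairs[0][0]
    for lm, _ in pairs:
        if lm.A.shape[1] != first.A.shape[1]:
            raise ValueError("lag matrices have mismatched column counts")
        if (lm.n_channels, lm.n_lags) != (first.n_channels, first.n_lags):
            raise ValueError("lag matrices have mismatched channel/lag layout")
    A = np.vstack([lm.A for lm, _ in pairs])
    y = np.concatenate([np.asarray(t, dtype=float).ravel() for _, t in pairs])
    if A.shape[0] != y.size:
        raise ValueError("row/target count mismatch after concatenation")
    return LagMatrix(A=A, n_channels=first.n_channels, n_lags=first.n_lags), y


def subsample_channels(rec: EEGRecording, target_labels) -> EEGRecording:
    """Select (and reorder) channels by label, e.g. wet -> dry subset."""
    target_labels = list(target_labels)
    missing = [l for l in target_labels if l not in rec.channel_labels]
    if missing:
        raise KeyError(f"labels missing from recording: {missing}")
    idx = [rec.channel_labels.index(l) for l in target_labels]
    positions = None
    if rec.channel_positions is not None:
        positions = np.asarray(rec.channel_positions)[idx]
    return EEGRecording(
        data=rec.data[idx],
        fs=rec.fs,
        channel_labels=target_labels,
        channel_positions=positions,
    )
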