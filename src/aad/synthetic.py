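"""Synthetic two-talker listening sessions with known ground truth.

The generator emulates the structure of a two-talker attention experiment:
a session of several "parts" (uninterrupted listening intervals of tens of
seconds), two concurrent speech-envelope streams, and EEG that encodes the
attended stream more strongly than the unattended one.

Generative model, per channel c:

    eeg_c(t) = topo_c * [ (h * env_att)(t) + g_u * (h * env_unatt)(t) ]
               + noise_c(t)

* ``h`` is a difference-of-Gaussians kernel with its positive peak at the
  configured latency (default 200 ms, the dominant latency of attended-
  speech temporal response functions) and support within 400 ms.
* ``topo_c`` is a smooth radial gain centered at the vertex (Cz), mimicking
  the central-scalp topography of the auditory response.
* ``g_u`` (default 0.3) scales the unattended stream; ``g_u = 1`` removes
  all attention information, ``g_u = 0`` encodes the attended stream only.
* ``noise_c`` is independent per channel with a 1/f spectrum (exponent 1.0,
  the canonical EEG background) scaled to a per-channel SNR in dB.
* The output is band-limited to 2-32 Hz at 100 Hz, like preprocessed EEG.

Envelope streams are low-pass filtered rectified noise: non-negative, with
dominant energy below 8 Hz like broadband speech envelopes, and independent
between talkers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import Envelope, EEGRecording, Session
from .montages import get_montage, montage_positions

FS = 100.0


@dataclass
class SimulationConfig:
    montage: str = "wet"                      # 'wet' (64), 'dry' (18), 'custom'
    custom_labels: tuple[str, ...] | None = None
    n_parts: int = 8
    part_duration_s: tuple[float, float] = (20.0, 60.0)
    peak_latency_s: float = 0.2
    kernel_width_s: float = 0.03
    attended_gain: float = 1.0
    unattended_gain: float = 0.3
    snr_db: float = 0.0
    noise_exponent: float = 1.0
    topo_width: float = 0.35
    topo_floor: float = 0.1
    talkers: tuple[str, str] = ("talker_f", "talker_m")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.unattended_gain <= 1.0):
            raise ValueError("unattended gain must be in [0, 1]")
        if self.unattended_gain > self.attended_gain:
            raise ValueError("unattended gain must not exceed attended gain")
        if np.isnan(self.snr_db):
            raise ValueError("SNR must be finite or +inf")
        if self.part_duration_s[0] < 1.0:
            raise ValueError("part durations must be >= 1 s")

    def labels_positions(self):
        if self.montage == "custom":
            if not self.custom_labels:
                raise ValueError("custom montage needs custom_labels")
            return tuple(self.custom_labels), montage_positions(self.custom_labels)
        return get_montage(self.montage)


def generate_envelope_pair(duration_s: float, fs: float = FS,
                           rng: np.random.Generator | int | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Two independent non-negative speech-like envelope processes."""
    if duration_s < 1.0:
        raise ValueError("duration must be >= 1 s")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = int(round(duration_s * fs))
    sos = signal.butter(4, 6.0, btype="low", fs=fs, output="sos")
    out = []
    for _ in range(2):
        rect = np.abs(rng.standard_normal(n))
        env = signal.sosfiltfilt(sos, rect)
        out.append(np.clip(env, 0.0, None))
    return out[0], out[1]


def response_kernel(cfg: SimulationConfig, fs: float = FS) -> np.ndarray:
    """Difference-of-Gaussians forward kernel, positive peak at the latency."""
    t = np.arange(0.0, 0.4 + 1.0 / fs, 1.0 / fs)
    mu = cfg.peak_latency_s
    s1 = cfg.kernel_width_s
    s2 = 2.5 * cfg.kernel_width_s
    h = np.exp(-((t - mu) ** 2) / (2 * s1**2)) - 0.5 * np.exp(
        -((t - mu) ** 2) / (2 * s2**2)
    )
    return h


def vertex_topography(positions: np.ndarray, width: float = 0.35,
                      floor: float = 0.1) -> np.ndarray:
    """Smooth radial gain centered at the vertex (head center)."""
    d2 = (np.asarray(positions, dtype=float) ** 2).sum(axis=1)
    return floor + np.exp(-d2 / (2 * width**2))


def _one_over_f_noise(n_channels: int, n_samples: int, exponent: float,
                      rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / FS)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    return np.fft.irfft(spec * shaping, n=n_samples, axis=1)


def forward_encode(env_att: np.ndarray, env_unatt: np.ndarray,
                   cfg: SimulationConfig,
                   rng: np.random.Generator | int | None = None
                   ) -> tuple[EEGRecording, dict]:
    """Encode two envelope streams into band-limited multichannel EEG.

    Returns the recording and a dict with the realized per-channel signal
    and noise powers (for SNR audits).
    """
    env_att = np.asarray(env_att, dtype=float)
    env_unatt = np.asarray(env_unatt, dtype=float)
    if env_att.shape != env_unatt.shape:
        raise ValueError("envelope streams must have equal length")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    labels, positions = cfg.labels_positions()
    topo = vertex_topography(positions, cfg.topo_width, cfg.topo_floor)
    h = response_kernel(cfg)
    n = env_att.size
    drive = (cfg.attended_gain * np.convolve(env_att - env_att.mean(), h)[:n]
             + cfg.unattended_gain
             * np.convolve(env_unatt - env_unatt.mean(), h)[:n])
    sos = signal.butter(4, [2.0, 32.0], btype="bandpass", fs=FS, output="sos")
    drive = signal.sosfiltfilt(sos, drive)
    sig = topo[:, None] * drive[None, :]
    sig_power = (sig**2).mean(axis=1)
    if np.isinf(cfg.snr_db):
        noise = np.zeros_like(sig)
        noise_power = np.zeros(len(labels))
    else:
        noise = _one_over_f_noise(len(labels), n, cfg.noise_exponent, rng)
        noise = signal.sosfiltfilt(sos, noise, axis=1)
        raw_power = (noise**2).mean(axis=1)
        if np.all(sig_power == 0):
            # pure-noise mode (zero gains): unit-power 1/f background
            target_power = np.ones_like(raw_power)
        else:
            target_power = sig_power * 10.0 ** (-cfg.snr_db / 10.0)
        noise *= np.sqrt(target_power / raw_power)[:, None]
        noise_power = (noise**2).mean(axis=1)
    rec = EEGRecording(data=sig + noise, fs=FS, channel_labels=list(labels),
                       channel_positions=positions)
    info = {"signal_power": sig_power, "noise_power": noise_power,
            "topography": topo, "kernel": h}
    return rec, info


def generate_session(cfg: SimulationConfig, subject_id: str = "sim") -> Session:
    """Generate a full session: parts, envelopes, EEG, and ground truth.

    The attended talker is randomized per part (seeded).  The session is a
    continuous timeline; part boundaries are stored in ``parts_index``.
    """
    rng = np.random.default_rng(cfg.seed)
    labels, positions = cfg.labels_positions()
    t_f, t_m = cfg.talkers
    eeg_chunks, env_f_chunks, env_m_chunks = [], [], []
    parts_index: list[tuple[int, int, str]] = []
    gt_parts = []
    cursor = 0
    lo, hi = cfg.part_duration_s
    for _ in range(cfg.n_parts):
        duration = float(rng.uniform(lo, hi))
        env_a, env_b = generate_envelope_pair(duration, rng=rng)
        attended = t_f if rng.random() < 0.5 else t_m
        env_f, env_m = (env_a, env_b)
        env_att, env_unatt = (env_f, env_m) if attended == t_f else (env_m, env_f)
        rec, info = forward_encode(env_att, env_unatt, cfg, rng=rng)
        n = rec.n_samples
        eeg_chunks.append(rec.data)
        env_f_chunks.append(env_f)
        env_m_chunks.append(env_m)
        parts_index.append((cursor, cursor + n, attended))
        with np.errstate(divide="ignore"):
            realized = 10.0 * np.log10(info["signal_power"]
                                       / np.where(info["noise_power"] > 0,
                                                  info["noise_power"], np.nan))
        gt_parts.append({
            "attended": attended,
            "realized_snr_db": realized,
        })
        cursor += n
    eeg = EEGRecording(
        data=np.hstack(eeg_chunks), fs=FS, channel_labels=list(labels),
        channel_positions=positions,
    )
    ground_truth = {
        "config": cfg,
        "kernel": response_kernel(cfg),
        "topography": vertex_topography(positions, cfg.topo_width,
                                        cfg.topo_floor),
        "parts": gt_parts,
    }
    return Session(
        subject_id=subject_id,
        eeg=eeg,
        envelopes={
            t_f: Envelope(np.concatenate(env_f_chunks), talker_id=t_f),
            t_m: Envelope(np.concatenate(env_m_chunks), talker_id=t_m),
        },
        parts_index=parts_index,
        ground_truth=ground_truth,
    )
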