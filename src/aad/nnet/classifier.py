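"""End-to-end convolutional attention classifier.

Instead of reconstructing the stimulus and correlating it with each
candidate, this network scores the similarity between a 10-second EEG window
and one candidate envelope directly.  The candidate envelope is appended to
the EEG as an extra input row, the 1000-sample window is randomly
downsampled by a factor of four to 250 samples, and the stack is pushed
through:

    BN -> Conv1(k=3) -> ELU -> DO -> Conv2(k=1, 2 ch) -> ELU
       -> MaxPool(k=3, s=2) -> flatten (246)
       -> [BN -> FC -> ELU -> DO] x 3 -> FC4 -> scalar score

For a 250-sample input the temporal chain is 250 -> 248 (conv k3, valid)
-> 248 (conv k1) -> 123 (pool k3 s2); times the 2 Conv2 output channels
gives the 246 features entering FC1, for any montage.  Conv1 emits 64
channels in wet (65-row input) mode and 19 in dry (19-row input) mode.

Training: binary cross-entropy on balanced (attended=1 / unattended=0)
window pairs, Adam, lr 1e-3, batch 1024, no weight decay, halting at the
first step whose training loss drops below 0.09 or at step 2400.  The
4x downsampling is re-drawn at every presentation.  At test time the two
candidates of a window share one seeded downsampling draw so their scores
are comparable; the sigmoid lives inside the loss, and decisions compare
raw scores (monotone equivalent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .layers import (Adam, BatchNorm, Conv1d, Dropout, ELU, Flatten, Linear,
                     MaxPool1d, Sequential, bce_with_logits)

WINDOW_SAMPLES = 1000  #: 10 s at 100 Hz
DOWNSAMPLED = 250      #: after 4x random downsampling


@dataclass
class ClassifierConfig:
    n_eeg_channels: int
    conv1_out: int | None = None  # 64 wet / 19 dry; default inferred
    conv1_kernel: int = 3
    conv2_out: int = 2
    pool_kernel: int = 3
    pool_stride: int = 2
    fc_sizes: tuple[int, ...] = (200, 200, 100)
    dropout: float = 0.25
    learning_rate: float = 1e-3
    batch_size: int = 1024
    max_steps: int = 2400
    loss_stop: float = 0.09
    downsample_factor: int = 4

    def __post_init__(self) -> None:
        if self.n_eeg_channels < 1:
            raise ValueError("need at least one EEG channel")
        if self.conv1_out is None:
            if self.n_eeg_channels == 64:
                self.conv1_out = 64
            elif self.n_eeg_channels == 18:
                self.conv1_out = 19
            else:
                self.conv1_out = self.n_eeg_channels

    @property
    def in_channels(self) -> int:
        return self.n_eeg_channels + 1  # EEG rows + appended envelope row

    @property
    def flattened(self) -> int:
        L = DOWNSAMPLED - self.conv1_kernel + 1   # conv1, valid
        L = L - 1 + 1                             # conv2, kernel 1
        L = (L - self.pool_kernel) // self.pool_stride + 1
        return L * self.conv2_out


@dataclass
class LabelledWindow:
    """A 10-s EEG window stacked with one candidate envelope row.

    ``window`` is (n_eeg_channels + 1, 1000), robust-scaled, with the
    envelope as the last row; the 4x random downsampling to 250 samples is
    applied at presentation time (re-drawn every time the example is seen).
    ``label`` is 1 when the candidate is the attended stream.
    """

    window: np.ndarray
    label: int
    part_id: str = ""
    window_index: int = -1

    def __post_init__(self) -> None:
        if self.window.shape[1] != WINDOW_SAMPLES:
            raise ValueError("window must have 1000 time samples")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def random_downsample(window: np.ndarray, factor: int = 4,
                      rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Keep 1/factor of the time samples, uniformly without replacement.

    The surviving indices are sorted ascending and shared by all channels.
    """
    window = np.asarray(window, dtype=float)
    L = window.shape[-1]
    if L % factor != 0:
        raise ValueError(f"window length {L} not divisible by factor {factor}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    idx = np.sort(rng.choice(L, size=L // factor, replace=False))
    return window[..., idx]


class ConvClassifier:
    """The convolutional similarity network with its training state."""

    def __init__(self, cfg: ClassifierConfig, seed: int = 0):
        if cfg.flattened != 246:
            # the printed architecture pins this; any deviation is a config bug
            raise ValueError(
                f"flattened feature count {cfg.flattened} != 246"
            )
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        layers = [
            BatchNorm(cfg.in_channels, axis="channel", name="bn0"),
            Conv1d(cfg.in_channels, cfg.conv1_out, cfg.conv1_kernel, rng,
                   name="conv1"),
            ELU(),
            Dropout(cfg.dropout),
            Conv1d(cfg.conv1_out, cfg.conv2_out, 1, rng, name="conv2"),
            ELU(),
            MaxPool1d(cfg.pool_kernel, cfg.pool_stride),
            Flatten(),
        ]
        in_dim = cfg.flattened
        for i, out_dim in enumerate(cfg.fc_sizes, start=1):
            layers += [
                BatchNorm(in_dim, name=f"bn_fc{i}"),
                Linear(in_dim, out_dim, rng, name=f"fc{i}"),
                ELU(),
                Dropout(cfg.dropout),
            ]
            in_dim = out_dim
        layers.append(Linear(in_dim, 1, rng, name=f"fc{len(cfg.fc_sizes) + 1}"))
        self.net = Sequential(*layers)
        self.loss_history: list[float] = []
        self.stop_step: int | None = None

    def parameters(self):
        return self.net.parameters()

    @property
    def conv1(self) -> Conv1d:
        return self.net.layers[1]

    def score(self, x: np.ndarray, train: bool = False,
              rng: np.random.Generator | None = None) -> np.ndarray:
        """Raw (pre-sigmoid) similarity scores for (batch, C+1, 250) input."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.shape[-1] != DOWNSAMPLED:
            raise ValueError(
                f"expected {DOWNSAMPLED}-sample input, got {x.shape[-1]}"
            )
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input rows, got {x.shape[1]}"
            )
        return self.net.forward(x, train, rng).ravel()


def build_classifier(cfg: ClassifierConfig, seed: int = 0) -> ConvClassifier:
    return ConvClassifier(cfg, seed=seed)


def make_training_pairs(windows) -> list[LabelledWindow]:
    """Expand (eeg_window, env_att, env_unatt) triples into balanced pairs.

    ``windows`` yields tuples ``(eeg: (C, 1000), env_att: (1000,),
    env_unatt: (1000,), part_id, window_index)`` of robust-scaled signals.
    Every window contributes exactly two examples: the attended candidate
    labelled 1 and the unattended candidate labelled 0.
    """
    pairs: list[LabelledWindow] = []
    for eeg, env_att, env_unatt, part_id, wi in windows:
        eeg = np.asarray(eeg, dtype=float)
        for env, label in ((env_att, 1), (env_unatt, 0)):
            stacked = np.vstack([eeg, np.asarray(env, dtype=float)[None, :]])
            pairs.append(LabelledWindow(stacked, label, part_id, wi))
    return pairs


def train_classifier(model: ConvClassifier, pairs: list[LabelledWindow],
                     seed: int = 0) -> ConvClassifier:
    """Train in place; halts at loss < cfg.loss_stop or cfg.max_steps."""
    cfg = model.cfg
    if not pairs:
        raise ValueError("no training pairs")
    labels = np.array([p.label for p in pairs], dtype=float)
    if labels.min() == labels.max():
        raise ValueError("need at least one positive and one negative example")
    X = np.stack([p.window for p in pairs])  # (n, C+1, 1000)
    n = X.shape[0]
    batch = min(cfg.batch_size, n)
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    model.loss_history = []
    model.stop_step = None
    for step in range(1, cfg.max_steps + 1):
        bidx = rng.choice(n, size=batch, replace=False)
        # fresh per-example 4x downsampling at every presentation
        keep = np.sort(
            np.array([rng.choice(WINDOW_SAMPLES, size=DOWNSAMPLED,
                                 replace=False) for _ in range(batch)]),
            axis=1,
        )
        xb = np.take_along_axis(X[bidx], keep[:, None, :], axis=2)
        scores = model.net.forward(xb, True, rng).ravel()
        loss, grad = bce_with_logits(scores, labels[bidx], with_grad=True)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite training loss at step {step}")
        model.loss_history.append(float(loss))
        model.net.zero_grad()
        model.net.backward(grad.reshape(-1, 1))
        opt.step()
        if loss < cfg.loss_stop:
            model.stop_step = step
            break
    else:
        model.stop_step = cfg.max_steps
    return model


def classify_window(model: ConvClassifier, eeg_window: np.ndarray,
                    env_a: np.ndarray, env_b: np.ndarray,
                    rng: np.random.Generator | int | None = None,
                    n_draws: int = 1):
    """Score both candidates for one 1000-sample window; pick the larger.

    Both candidates share the same downsampling draw(s); with ``n_draws > 1``
    scores are averaged over several draws.  Returns
    ``(score_a, score_b, decision)`` with decision 0 for candidate A.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    eeg_window = np.asarray(eeg_window, dtype=float)
    if eeg_window.shape[1] != WINDOW_SAMPLES:
        raise ValueError("window must have 1000 time samples")
    stack_a = np.vstack([eeg_window, np.asarray(env_a, dtype=float)[None, :]])
    stack_b = np.vstack([eeg_window, np.asarray(env_b, dtype=float)[None, :]])
    score_a = score_b = 0.0
    for _ in range(n_draws):
        keep = np.sort(rng.choice(WINDOW_SAMPLES, size=DOWNSAMPLED,
                                  replace=False))
        score_a += float(model.score(stack_a[:, keep])[0])
        score_b += float(model.score(stack_b[:, keep])[0])
    score_a /= n_draws
    score_b /= n_draws
    if score_a == score_b:
        warnings.warn("tied classifier scores; declaring candidate A")
        decision = 0
    else:
        decision = 0 if score_a > score_b else 1
    return score_a, score_b, decision


def conv1_channel_importance(model: ConvClassifier) -> np.ndarray:
    """Per-input-row importance from the first convolution's middle tap.

    Takes the middle element of the 3-point temporal kernel, its absolute
    value, and sums over output channels, yielding one value per input row
    (EEG channels plus the trailing envelope row).  EEG entries are min-max
    normalized to [0, 1]; the same affine transform is applied to the audio
    entry, which may therefore exceed 1.
    """
    W = model.conv1.W.value  # (out, in, k)
    if W.shape[2] != 3:
        raise ValueError("channel importance requires a 3-tap first kernel")
    raw = np.abs(W[:, :, 1]).sum(axis=0)  # one value per input row
    eeg, audio = raw[:-1], raw[-1]
    lo, hi = eeg.min(), eeg.max()
    if hi == lo:
        warnings.warn("degenerate min-max (all EEG weights equal); returning zeros")
        out = np.zeros_like(raw)
        return out
    out = (raw - lo) / (hi - lo)
    return out
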