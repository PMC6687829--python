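"""Stimulus-reconstruction neural network.

A deliberately small architecture: the lagged EEG context window is
compressed through a single hidden layer of two nodes before being expanded
back to one predicted envelope sample, with batch normalization before each
layer's input and a hard hyperbolic tangent on the output so the prediction
is bounded like an (appropriately normalized) audio envelope:

    BN -> FC(input_dim -> 2) -> tanh -> BN -> FC(2 -> 1) -> hard tanh

Training minimizes ``1 - pearson_r`` per mini-batch (the same statistic that
later scores attention decisions), with Adam, batch size 1024, learning rate
1e-3, no weight decay, 2400 mini-batch steps.

Targets: the robust-scaled envelope is clipped to [-3, 3] and divided by 3
so it lives in the hard-tanh output range; predictions are mapped back with
the inverse transform.  (Pearson-based evaluation is itself invariant to
this affine map; it only matters for training dynamics.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Adam, BatchNorm, HardTanh, Linear, Sequential, Tanh, pearson_loss

TARGET_CLIP = 3.0


@dataclass
class ReconNetConfig:
    input_dim: int
    hidden_units: int = 2
    learning_rate: float = 1e-3
    batch_size: int = 1024
    iterations: int = 2400
    hidden_activation: str = "tanh"

    def __post_init__(self) -> None:
        if self.input_dim <= 0:
            raise ValueError("input_dim must be positive")
        if self.hidden_units != 2:
            raise ValueError("the reference architecture uses exactly 2 hidden units")


class ReconstructionNet:
    """Two-node bottleneck reconstruction network with its training state."""

    def __init__(self, cfg: ReconNetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.net = Sequential(
            BatchNorm(cfg.input_dim, name="bn0"),
            Linear(cfg.input_dim, cfg.hidden_units, rng, name="fc1"),
            Tanh(),
            BatchNorm(cfg.hidden_units, name="bn1"),
            Linear(cfg.hidden_units, 1, rng, name="fc2"),
            HardTanh(),
        )
        self.loss_history: list[float] = []

    def parameters(self):
        return self.net.parameters()

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def forward(self, A: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Bounded network output in [-1, 1] for a (rows, input_dim) batch."""
        return self.net.forward(np.asarray(A, dtype=float), train, rng).ravel()

    def predict(self, A: np.ndarray) -> np.ndarray:
        """Reconstructed envelope on the robust-scaled target scale."""
        return self.forward(A, train=False) * TARGET_CLIP


def build_reconstruction_net(cfg: ReconNetConfig, seed: int = 0) -> ReconstructionNet:
    return ReconstructionNet(cfg, seed=seed)


def scale_target(y_scaled: np.ndarray) -> np.ndarray:
    """Map a robust-scaled envelope into the hard-tanh range [-1, 1]."""
    return np.clip(np.asarray(y_scaled, dtype=float), -TARGET_CLIP, TARGET_CLIP) / TARGET_CLIP


def train_reconstruction(model: ReconstructionNet, A: np.ndarray,
                         y: np.ndarray, seed: int = 0) -> ReconstructionNet:
    """Train in place with per-mini-batch correlation loss; seeded.

    ``y`` must already be on the robust-scaled target scale; it is mapped
    into [-1, 1] here.  Runs exactly ``cfg.iterations`` Adam steps on random
    mini-batches of ``cfg.batch_size`` rows (all rows if fewer are
    available).  The loss history is recorded on ``model.loss_history``.
    """
    cfg = model.cfg
    A = np.asarray(A, dtype=float)
    t = scale_target(y)
    if A.shape[0] != t.size:
        raise ValueError("A rows and target length differ")
    n = A.shape[0]
    batch = min(cfg.batch_size, n)
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    model.loss_history = []
    for step in range(cfg.iterations):
        idx = rng.choice(n, size=batch, replace=False)
        pred = model.net.forward(A[idx], True, rng).ravel()
        loss, grad = pearson_loss(pred, t[idx], with_grad=True)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite training loss at step {step}: {loss}"
            )
        model.loss_history.append(float(loss))
        model.net.zero_grad()
        model.net.backward(grad.reshape(-1, 1))
        opt.step()
    return model
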