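"""Regularized linear backward model (inverse TRF).

The decoder solves ``w = argmin ||A w - y||^2 + lam ||w||^2`` in closed form,
``w = (A'A + lam I)^{-1} A'y``, on robust-scaled inputs with no intercept.
The regularization strength is chosen from ten logarithmically spaced values
between 1e1 and 1e10 by internal 3-fold cross-validation at the part level,
scored with the Pearson correlation of validation predictions against the
validation target (ties resolved toward the smaller lambda).

``w`` reshapes to (n_channels, n_lags) under the channel-major column order
of the design matrix; in the backward direction these weights form an
inverse temporal response function (TRF).

An optional gradient-based estimator that minimizes ``1 - pearson_r`` of the
linear prediction directly is provided as :func:`fit_linear_correlation`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import LagMatrix

LAMBDA_GRID = np.logspace(1.0, 10.0, 10)  #: 1e1 .. 1e10, 10 values


@dataclass
class DecoderWeights:
    """Flat inverse-TRF weight vector with its (channels, lags) layout."""

    w: np.ndarray
    n_channels: int
    n_lags: int
    lambda_selected: float | None = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float).ravel()
        if self.w.size != self.n_channels * self.n_lags:
            raise ValueError("weight length != n_channels * n_lags")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("non-finite decoder weights")


def fit_ridge(A: LagMatrix | np.ndarray, y: np.ndarray, lam: float,
              n_channels: int | None = None,
              n_lags: int | None = None) -> DecoderWeights:
    """Closed-form ridge solution on a (rows, channels*lags) design matrix."""
    if isinstance(A, LagMatrix):
        n_channels, n_lags = A.n_channels, A.n_lags
        A = A.A
    elif n_channels is None or n_lags is None:
        raise ValueError("n_channels and n_lags required for a raw array")
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if A.shape[0] != y.size:
        raise ValueError("A rows and y length differ")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    G = A.T @ A
    b = A.T @ y
    w = _solve_ridge(G, b, lam)
    return DecoderWeights(w=w, n_channels=n_channels, n_lags=n_lags,
                          lambda_selected=lam)


def _solve_ridge(G: np.ndarray, b: np.ndarray, lam: float) -> np.ndarray:
    M = G + lam * np.eye(G.shape[0])
    try:
        w = np.linalg.solve(M, b)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular normal equations at lam={lam}; use lam > 0"
        ) from exc
    if lam == 0 and not np.all(np.isfinite(w)):
        raise np.linalg.LinAlgError("singular system at lam=0; use lam > 0")
    return w


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def select_lambda(part_matrices, grid: np.ndarray = LAMBDA_GRID,
                  n_folds: int = 3, seed: int = 0) -> float:
    """Choose lambda by part-level K-fold CV scored with Pearson correlation.

    ``part_matrices`` is a list of per-part ``(LagMatrix, target)`` pairs.
    Folds are groups of whole parts (a seeded shuffle then round-robin), so
    no fold mixes samples across a part boundary.  For each lambda the mean
    over folds of the correlation between validation predictions and the
    validation target is computed; the best lambda wins, ties going to the
    smaller value.
    """
    part_matrices = list(part_matrices)
    grid = np.asarray(grid, dtype=float)
    if len(part_matrices) < n_folds:
        raise ValueError(
            f"need >= {n_folds} training parts for {n_folds}-fold lambda "
            f"selection (got {len(part_matrices)}); reduce n_folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(part_matrices))
    folds = [list(order[i::n_folds]) for i in range(n_folds)]

    # Per-part sufficient statistics are computed once; every fold/lambda
    # combination is then a cheap solve.
    Gs = [lm.A.T @ lm.A for lm, _ in part_matrices]
    bs = [lm.A.T @ np.asarray(t, dtype=float) for lm, t in part_matrices]

    scores = np.zeros(grid.size)
    for fold in folds:
        train = [i for i in range(len(part_matrices)) if i not in fold]
        G = sum(Gs[i] for i in train)
        b = sum(bs[i] for i in train)
        A_val = np.vstack([part_matrices[i][0].A for i in fold])
        y_val = np.concatenate(
            [np.asarray(part_matrices[i][1], dtype=float) for i in fold]
        )
        for j, lam in enumerate(grid):
            w = _solve_ridge(G, b, lam)
            scores[j] += _pearson(A_val @ w, y_val)
    scores /= len(folds)
    best = np.flatnonzero(scores == scores.max())[0]  # tie -> smaller lambda
    return float(grid[best])


def fit_ridge_from_parts(part_matrices, lam: float) -> DecoderWeights:
    """Ridge fit from per-part (LagMatrix, target) pairs via summed Grams.

    Algebraically identical to :func:`fit_ridge` on the row-stacked matrix
    (A'A and A'y are additive over row blocks) but avoids materializing the
    concatenated design matrix.
    """
    part_matrices = list(part_matrices)
    if not part_matrices:
        raise ValueError("no parts")
    lm0 = part_matrices[0][0]
    G = sum(lm.A.T @ lm.A for lm, _ in part_matrices)
    b = sum(lm.A.T @ np.asarray(t, dtype=float) for lm, t in part_matrices)
    w = _solve_ridge(G, b, lam)
    return DecoderWeights(w=w, n_channels=lm0.n_channels, n_lags=lm0.n_lags,
                          lambda_selected=lam)


def predict_envelope(w: DecoderWeights, A: LagMatrix | np.ndarray) -> np.ndarray:
    """Reconstruct the envelope: ``y_hat = A w``."""
    if isinstance(A, LagMatrix):
        A = A.A
    A = np.asarray(A, dtype=float)
    if A.shape[1] != w.w.size:
        raise ValueError(
            f"design matrix has {A.shape[1]} columns, weights have {w.w.size}"
        )
    return A @ w.w


def expand_trf(w: DecoderWeights) -> np.ndarray:
    """Reshape flat weights to (n_channels, n_lags) (channel-major order)."""
    return w.w.reshape(w.n_channels, w.n_lags)


def fit_linear_correlation(A: LagMatrix | np.ndarray, y: np.ndarray,
                           n_channels: int | None = None,
                           n_lags: int | None = None,
                           lr: float = 1e-2, n_steps: int = 2000,
                           seed: int = 0) -> DecoderWeights:
    """Linear fit minimizing ``1 - pearson_r(Aw, y)`` by full-batch Adam.

    Alternative estimator for the linear backward model; the ridge closed
    form remains the default.
    """
    if isinstance(A, LagMatrix):
        n_channels, n_lags = A.n_channels, A.n_lags
        A = A.A
    elif n_channels is None or n_lags is None:
        raise ValueError("n_channels and n_lags required for a raw array")
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    yc = y - y.mean()
    sy = np.sqrt(yc @ yc)
    if sy == 0:
        raise ValueError("constant target: correlation undefined")
    rng = np.random.default_rng(seed)
    w = rng.normal(scale=1e-3, size=A.shape[1])
    m = np.zeros_like(w)
    v = np.zeros_like(w)
    b1, b2, eps = 0.9, 0.999, 1e-8
    for t in range(1, n_steps + 1):
        p = A @ w
        pc = p - p.mean()
        sp = np.sqrt(pc @ pc) + 1e-12
        r = (pc @ yc) / (sp * sy)
        # d(1-r)/dp, then chain through A
        gp = -(yc / (sp * sy) - r * pc / sp**2)
        gp -= gp.mean()
        g = A.T @ gp
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        mhat = m / (1 - b1**t)
        vhat = v / (1 - b2**t)
        w -= lr * mhat / (np.sqrt(vhat) + eps)
    return DecoderWeights(w=w, n_channels=n_channels, n_lags=n_lags)
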