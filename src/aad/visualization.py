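"""TRF and channel-importance headmaps.

Two grand-averaging procedures are implemented, both built on min-max
normalization to [0, 1]:

* TRF maps: each subject's full (channels x lags) inverse-TRF array is
  min-max normalized as a whole (one min and max per subject, so relative
  strength across lags survives), subjects are averaged, and the average is
  re-normalized to [0, 1]; one headmap is emitted per lag.
* Classifier channel importance: per subject, the EEG entries of the
  importance vector are min-max normalized and the *same* affine transform
  is applied to the trailing audio entry; subjects are averaged and the
  EEG-only re-normalization (again applied to the audio entry) is repeated.
  The audio value may exceed 1, signifying that audio outweighs every EEG
  lead.

Rendering uses radial-basis interpolation clipped to the head circle -- a
deliberately simple scheme; figure aesthetics are not a goal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.interpolate import RBFInterpolator


@dataclass
class Headmap:
    values: np.ndarray            # per-channel, in [0, 1] after normalization
    positions: np.ndarray         # (n, 2) scalp coordinates
    audio_value: float | None = None   # may exceed 1
    time_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape[0] != self.values.size:
            raise ValueError("positions/values count mismatch")


def normalize_minmax(values: np.ndarray) -> np.ndarray:
    """Affine map of values onto [0, 1]; constant input -> zeros + warning."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    lo, hi = values.min(), values.max()
    if hi == lo:
        warnings.warn("constant input to min-max normalization; returning zeros")
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def grand_average_trf_maps(per_subject_trfs, positions: np.ndarray,
                           fs: float = 100.0) -> list[Headmap]:
    """Grand-average normalized TRF headmaps, one per lag.

    ``per_subject_trfs`` is a list of (channels, lags) arrays sharing one
    montage and lag count.
    """
    trfs = [np.asarray(t, dtype=float) for t in per_subject_trfs]
    if not trfs:
        raise ValueError("no subjects")
    shape = trfs[0].shape
    if any(t.shape != shape for t in trfs):
        raise ValueError("subjects have mismatched montage or lag count")
    normalized = [normalize_minmax(t) for t in trfs]
    avg = np.mean(normalized, axis=0)
    final = normalize_minmax(avg)
    return [
        Headmap(values=final[:, lag], positions=positions,
                time_label=f"{lag / fs * 1000:.0f} ms")
        for lag in range(shape[1])
    ]


def _normalize_with_audio(vec: np.ndarray) -> np.ndarray:
    """EEG-only min-max, with the same affine transform on the audio entry."""
    vec = np.asarray(vec, dtype=float)
    eeg = vec[:-1]
    lo, hi = eeg.min(), eeg.max()
    if hi == lo:
        warnings.warn("degenerate EEG min-max; returning zeros")
        return np.zeros_like(vec)
    return (vec - lo) / (hi - lo)


def grand_average_importance(per_subject_vectors,
                             positions: np.ndarray) -> Headmap:
    """Grand-average classifier channel importance (EEG map + audio scalar).

    Each vector holds one value per EEG channel plus a trailing audio entry.
    """
    vecs = [np.asarray(v, dtype=float) for v in per_subject_vectors]
    if not vecs:
        raise ValueError("no subjects")
    size = vecs[0].size
    if any(v.size != size for v in vecs):
        raise ValueError("subjects have mismatched montage")
    avg = np.mean([_normalize_with_audio(v) for v in vecs], axis=0)
    final = _normalize_with_audio(avg)
    return Headmap(values=final[:-1], positions=positions,
                   audio_value=float(final[-1]))


def render_headmap(headmap: Headmap, out_path, grid: int = 128) -> None:
    """Write a PNG/SVG scalp map (RBF interpolation on the head disk)."""
    if headmap.positions.shape[0] < 4:
        raise ValueError("need at least 4 positioned channels to render")
    interp = RBFInterpolator(headmap.positions, headmap.values,
                             kernel="thin_plate_spline")
    xs = np.linspace(-1.05, 1.05, grid)
    xx, yy = np.meshgrid(xs, xs)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    zz = interp(pts).reshape(grid, grid)
    mask = xx**2 + yy**2 > 1.05**2
    zz = np.ma.masked_where(mask, zz)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.pcolormesh(xx, yy, zz, shading="auto", vmin=0.0, vmax=1.0,
                       cmap="viridis")
    ax.scatter(headmap.positions[:, 0], headmap.positions[:, 1],
               s=8, c="k", zorder=3)
    circle = plt.Circle((0, 0), 1.05, fill=False, color="k")
    ax.add_patch(circle)
    ax.set_aspect("equal")
    ax.set_axis_off()
    title = headmap.time_label
    if headmap.audio_value is not None:
        title = (title + " " if title else "") + f"audio={headmap.audio_value:.2f}"
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
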