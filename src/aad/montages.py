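"""Electrode montages and schematic 2-D scalp positions.

Two montages are built in:

* ``wet``  -- a 64-channel gel-cap layout (extended 10-10 naming) of the kind
  used by 64-channel research amplifiers.
* ``dry``  -- an 18-channel gel-free headset layout (10-20 naming).  The dry
  labels are a strict subset of the wet labels so that wet recordings can be
  sub-sampled channel-for-channel to the dry set.

Positions are schematic top-view scalp projections (nose up, left ear left)
inside the unit circle.  They are intended for topographic rendering and for
defining smooth simulated topographies, not for source analysis.
"""

from __future__ import annotations

import numpy as np

# Row letter -> anterior/posterior coordinate (front = +1).
_ROW_Y = {
    "Fp": 0.95,
    "AF": 0.75,
    "F": 0.55,
    "FT": 0.30,
    "FC": 0.30,
    "T": 0.00,
    "C": 0.00,
    "TP": -0.30,
    "CP": -0.30,
    "P": -0.55,
    "PO": -0.75,
    "O": -0.95,
    "I": -1.00,
    "M": -0.10,
}

# Column token -> left/right coordinate before squeezing into the head circle.
_COL_X = {
    "z": 0.0,
    "1": 0.22, "2": 0.22,
    "3": 0.45, "4": 0.45,
    "5": 0.68, "6": 0.68,
    "7": 0.90, "8": 0.90,
    "9": 1.05, "10": 1.05,
}

WET_LABELS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
    "FT9", "FT10", "Iz",
)

# 18-channel dry subset: full 10-20 scalp set minus the Pz midline electrode,
# keeping left/right symmetry (the dry headset records 18 scalp channels).
DRY_LABELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "P4", "P8", "O1", "O2",
)


def _split_label(label: str) -> tuple[str, str]:
    i = len(label)
    while i > 0 and (label[i - 1].isdigit() or label[i - 1] == "z"):
        i -= 1
    row, col = label[:i], label[i:]
    if col and col[-1] == "z" and len(col) > 1:  # no such case, safety
        row, col = label[:-1], "z"
    return row, col


def label_position(label: str) -> tuple[float, float]:
    """Schematic (x, y) scalp position of an electrode label."""
    row, col = _split_label(label)
    if row not in _ROW_Y or col not in _COL_X:
        raise KeyError(f"unknown electrode label: {label!r}")
    y = _ROW_Y[row]
    x = _COL_X[col]
    if col != "z" and int(col) % 2 == 1:
        x = -x
    # squeeze lateral extent toward the poles so points stay on the head disk
    x *= float(np.sqrt(max(1.0 - 0.55 * y * y, 0.05)))
    return x, y


def montage_positions(labels) -> np.ndarray:
    """(n, 2) array of schematic positions for a sequence of labels."""
    return np.array([label_position(l) for l in labels], dtype=float)


def get_montage(name: str) -> tuple[tuple[str, ...], np.ndarray]:
    """Return (labels, positions) for a named montage ('wet' or 'dry')."""
    if name == "wet":
        labels = WET_LABELS
    elif name == "dry":
        labels = DRY_LABELS
    else:
        raise ValueError(f"unknown montage {name!r}; expected 'wet' or 'dry'")
    return labels, montage_positions(labels)
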