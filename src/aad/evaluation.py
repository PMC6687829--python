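"""Evaluation protocol: part-level leave-one-out cross-validation, 10-second
windowed attention decisions, decoding accuracy, and binomial chance levels.

Accuracy is the fraction of non-overlapping 10-s windows for which the
attended candidate received the higher score (Pearson correlation with the
reconstruction, or the classifier's similarity score).  Chance level is the
95th-percentile point of Binomial(n, 0.5) over the subject's n windows: the
accuracy a guesser exceeds with only 5% probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Part

log = logging.getLogger(__name__)

WINDOW_SECONDS = 10.0


@dataclass
class WindowDecision:
    part_id: str
    window_index: int
    score_attended: float
    score_unattended: float
    correct: bool
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid and self.correct != (self.score_attended > self.score_unattended):
            raise ValueError("correct flag inconsistent with scores")


@dataclass
class SubjectResult:
    subject_id: str
    decoder: str
    montage: str
    accuracy: float
    n_windows: int
    chance_level: float
    decisions: list[WindowDecision] = field(default_factory=list)
    folds: list[dict] = field(default_factory=list)


def make_windows(part: Part, win_seconds: float = WINDOW_SECONDS) -> list[tuple[int, int]]:
    """Non-overlapping (start, stop) sample ranges of full windows in a part.

    The trailing remainder is dropped; a part shorter than one window yields
    an empty list (and is excluded from evaluation).
    """
    n_win_samples = int(round(win_seconds * part.eeg.fs))
    n = part.n_samples // n_win_samples
    return [(i * n_win_samples, (i + 1) * n_win_samples) for i in range(n)]


def _pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    va, vb = a @ a, b @ b
    if va == 0 or vb == 0:
        return None
    return float(a @ b / np.sqrt(va * vb))


def correlation_decision(recon: np.ndarray, env_att: np.ndarray,
                         env_unatt: np.ndarray, part_id: str = "",
                         window_index: int = -1) -> WindowDecision:
    """Compare one reconstructed window to both candidates by Pearson r.

    Correct iff r(recon, attended) > r(recon, unattended); an exact tie is
    conservatively incorrect.  A zero-variance window yields an invalid
    decision (excluded from accuracy) and is logged.
    """
    r_att = _pearson(recon, env_att)
    r_unatt = _pearson(recon, env_unatt)
    if r_att is None or r_unatt is None:
        log.warning("zero-variance window %s/%d excluded", part_id, window_index)
        return WindowDecision(part_id, window_index, np.nan, np.nan,
                              correct=False, valid=False)
    if r_att == r_unatt:
        log.warning("tied correlations in window %s/%d: counted incorrect",
                    part_id, window_index)
    return WindowDecision(part_id, window_index, r_att, r_unatt,
                          correct=r_att > r_unatt)


def decoding_accuracy(decisions) -> float:
    """Mean correctness over valid decisions; errors if none are valid."""
    valid = [d for d in decisions if d.valid]
    if not valid:
        raise ValueError("no valid window decisions")
    return float(np.mean([d.correct for d in valid]))


def chance_level(n_windows: int, p: float = 0.5, percentile: float = 0.95) -> float:
    """95th-percentile accuracy of a Binomial(n, p) guesser.

    Returns k*/n with k* the smallest k whose binomial CDF reaches the
    percentile.
    """
    if n_windows < 1:
        raise ValueError("need at least one window")
    k_star = int(stats.binom.ppf(percentile, n_windows, p))
    return k_star / n_windows


def loo_cross_validate(parts: list[Part], decoder_factory, seed: int = 0,
                       subject_id: str = "subject", decoder_name: str = "",
                       montage: str = "") -> SubjectResult:
    """Part-level leave-one-out cross-validation for one subject.

    For every evaluable part (>= one full window) a fresh decoder from
    ``decoder_factory()`` is fitted on all *other* parts — including its
    robust scalers and, for the linear decoder, its regularization selection
    — and produces window decisions on the held-out part.  Parts shorter
    than one window are excluded from evaluation but still used for
    training.
    """
    parts = list(parts)
    n_win = int(round(WINDOW_SECONDS * 100))
    evaluable = [i for i, p in enumerate(parts) if p.n_samples >= n_win]
    if len(evaluable) < 2:
        raise ValueError("need at least 2 evaluable parts for LOO-CV")
    decisions: list[WindowDecision] = []
    folds: list[dict] = []
    for k, i in enumerate(evaluable):
        train = [p for j, p in enumerate(parts) if j != i]
        fold_seed = int(np.random.default_rng([seed, k]).integers(2**31))
        decoder = decoder_factory()
        decoder.fit(train, seed=fold_seed)
        fold_decisions = decoder.evaluate_part(parts[i], seed=fold_seed)
        decisions.extend(fold_decisions)
        folds.append({
            "part_id": parts[i].part_id,
            "n_windows": len(fold_decisions),
            "artifacts": getattr(decoder, "fold_artifacts", {}),
        })
    acc = decoding_accuracy(decisions)
    n_valid = sum(d.valid for d in decisions)
    return SubjectResult(
        subject_id=subject_id,
        decoder=decoder_name or type(decoder).__name__,
        montage=montage,
        accuracy=acc,
        n_windows=n_valid,
        chance_level=chance_level(n_valid),
        decisions=decisions,
        folds=folds,
    )


def summarize(results: list[SubjectResult]) -> pd.DataFrame:
    """Mean and sample SD of accuracy across subjects per (decoder, montage).

    With a single subject the SD is reported as NaN (n/a).
    """
    if not results:
        raise ValueError("no results to summarize")
    df = pd.DataFrame(
        [{"subject": r.subject_id, "decoder": r.decoder, "montage": r.montage,
          "accuracy": r.accuracy, "n_windows": r.n_windows,
          "chance_level": r.chance_level} for r in results]
    )
    out = (df.groupby(["decoder", "montage"])["accuracy"]
           .agg(mean="mean", sd=lambda s: s.std(ddof=1), n_subjects="count")
           .reset_index())
    return out
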