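"""The three attention decoders behind a common fit/evaluate interface.

Each decoder owns its preprocessing state: robust scalers are fitted on the
training parts of the current cross-validation fold only, and (for the
linear decoder) the ridge regularization is re-selected inside every fold.

* :class:`LinearReconstructionDecoder` -- closed-form ridge inverse TRF.
* :class:`NetReconstructionDecoder` -- the two-node reconstruction network.
* :class:`ConvClassifierDecoder` -- the end-to-end convolutional classifier.

The reconstruction decoders are evaluated by correlating the reconstructed
envelope with both candidates over 10-s windows; the classifier scores both
candidates directly.  Reconstruction covers only the first ``T - L + 1``
samples of a part (rows needing EEG beyond the part end are dropped), so
reconstruction windows are cut on that truncated timeline; the classifier
sees the full part timeline.
"""

from __future__ import annotations

import numpy as np

from . import linear
from .containers import Part
from .evaluation import WindowDecision, correlation_decision, make_windows
from .nnet.classifier import (ClassifierConfig, ConvClassifier,
                              classify_window, make_training_pairs,
                              train_classifier)
from .nnet.reconstruction import (ReconNetConfig, ReconstructionNet,
                                  train_reconstruction)
from .preprocessing import (DEFAULT_N_LAGS, build_lag_matrix,
                            concatenate_part_matrices, fit_robust_scaler)

WINDOW_SAMPLES = 1000


def _fit_scalers(train_parts: list[Part], audio_both_streams: bool):
    """EEG scaler (per channel) and audio scaler fitted on training data.

    The audio scaler uses the attended stream only for reconstruction
    targets, or both streams when the envelopes are model *inputs* (the
    classifier sees both candidates).
    """
    eeg = np.hstack([p.eeg.data for p in train_parts]).T  # (T, C)
    eeg_scaler = fit_robust_scaler(eeg)
    if audio_both_streams:
        audio = np.concatenate(
            [np.concatenate([p.env_attended.values, p.env_unattended.values])
             for p in train_parts]
        )
    else:
        audio = np.concatenate([p.env_attended.values for p in train_parts])
    env_scaler = fit_robust_scaler(audio)
    return eeg_scaler, env_scaler


def _scaled_eeg(scaler, part: Part) -> np.ndarray:
    return scaler.transform(part.eeg.data.T).T  # back to (C, T)


class _ReconstructionDecoderBase:
    """Shared scaling / lag-matrix / correlation-evaluation plumbing."""

    def __init__(self, n_lags: int = DEFAULT_N_LAGS):
        self.n_lags = n_lags
        self.eeg_scaler = None
        self.env_scaler = None
        self.fold_artifacts: dict = {}

    def _train_matrices(self, train_parts: list[Part]):
        self.eeg_scaler, self.env_scaler = _fit_scalers(
            train_parts, audio_both_streams=False
        )
        per_part = []
        for p in train_parts:
            if p.n_samples < self.n_lags:
                continue
            lm, t = build_lag_matrix(
                _scaled_eeg(self.eeg_scaler, p), self.n_lags,
                target=self.env_scaler.transform(p.env_attended.values),
            )
            per_part.append((lm, t))
        if not per_part:
            raise ValueError("no usable training parts")
        return per_part

    def reconstruct(self, part: Part) -> np.ndarray:
        """Envelope reconstruction for samples 0 .. T - n_lags (inclusive)."""
        lm = build_lag_matrix(_scaled_eeg(self.eeg_scaler, part), self.n_lags)
        return self._predict(lm)

    def evaluate_part(self, part: Part, seed: int = 0) -> list[WindowDecision]:
        recon = self.reconstruct(part)
        n_win = recon.size // WINDOW_SAMPLES
        decisions = []
        for i in range(n_win):
            s, e = i * WINDOW_SAMPLES, (i + 1) * WINDOW_SAMPLES
            decisions.append(correlation_decision(
                recon[s:e], part.env_attended.values[s:e],
                part.env_unattended.values[s:e],
                part_id=part.part_id, window_index=i,
            ))
        return decisions


class LinearReconstructionDecoder(_ReconstructionDecoderBase):
    """Ridge inverse-TRF decoder with per-fold lambda selection.

    ``estimator='ridge'`` (default) uses the closed form; ``'correlation'``
    uses the gradient-based linear fit with the Pearson loss.
    """

    def __init__(self, n_lags: int = DEFAULT_N_LAGS,
                 grid: np.ndarray = linear.LAMBDA_GRID,
                 estimator: str = "ridge", cv_folds: int = 3):
        super().__init__(n_lags)
        if estimator not in ("ridge", "correlation"):
            raise ValueError("estimator must be 'ridge' or 'correlation'")
        self.grid = grid
        self.estimator = estimator
        self.cv_folds = cv_folds
        self.weights: linear.DecoderWeights | None = None

    def fit(self, train_parts: list[Part], seed: int = 0):
        per_part = self._train_matrices(train_parts)
        if self.estimator == "ridge":
            lam = linear.select_lambda(per_part, self.grid,
                                       n_folds=min(self.cv_folds, len(per_part)),
                                       seed=seed)
            self.weights = linear.fit_ridge_from_parts(per_part, lam)
        else:
            lm, y = concatenate_part_matrices(per_part)
            self.weights = linear.fit_linear_correlation(lm, y, seed=seed)
        self.fold_artifacts = {
            "lambda": self.weights.lambda_selected,
            "n_train_rows": sum(lm.n_rows for lm, _ in per_part),
        }
        return self

    def _predict(self, lm) -> np.ndarray:
        return linear.predict_envelope(self.weights, lm)


class NetReconstructionDecoder(_ReconstructionDecoderBase):
    """Two-node-bottleneck neural reconstruction decoder."""

    def __init__(self, n_lags: int = DEFAULT_N_LAGS, iterations: int = 2400,
                 batch_size: int = 1024, learning_rate: float = 1e-3):
        super().__init__(n_lags)
        self.iterations = iterations
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.model: ReconstructionNet | None = None

    def fit(self, train_parts: list[Part], seed: int = 0):
        per_part = self._train_matrices(train_parts)
        lm, y = concatenate_part_matrices(per_part)
        cfg = ReconNetConfig(
            input_dim=lm.A.shape[1],
            iterations=self.iterations,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
        )
        self.model = ReconstructionNet(cfg, seed=seed)
        train_reconstruction(self.model, lm.A, y, seed=seed)
        self.fold_artifacts = {
            "final_loss": self.model.loss_history[-1],
            "n_train_rows": lm.n_rows,
        }
        return self

    def _predict(self, lm) -> np.ndarray:
        return self.model.predict(lm.A)


class ConvClassifierDecoder:
    """End-to-end convolutional classifier decoder."""

    def __init__(self, conv1_out: int | None = None, dropout: float = 0.25,
                 max_steps: int = 2400, batch_size: int = 1024,
                 learning_rate: float = 1e-3, test_draws: int = 1):
        self.conv1_out = conv1_out
        self.dropout = dropout
        self.max_steps = max_steps
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.test_draws = test_draws
        self.model: ConvClassifier | None = None
        self.eeg_scaler = None
        self.env_scaler = None
        self.fold_artifacts: dict = {}

    def _window_triples(self, parts: list[Part]):
        for p in parts:
            eeg = _scaled_eeg(self.eeg_scaler, p)
            att = self.env_scaler.transform(p.env_attended.values)
            unatt = self.env_scaler.transform(p.env_unattended.values)
            for i, (s, e) in enumerate(make_windows(p)):
                yield eeg[:, s:e], att[s:e], unatt[s:e], p.part_id, i

    def fit(self, train_parts: list[Part], seed: int = 0):
        self.eeg_scaler, self.env_scaler = _fit_scalers(
            train_parts, audio_both_streams=True
        )
        pairs = make_training_pairs(self._window_triples(train_parts))
        if not pairs:
            raise ValueError("training parts yield no 10-s windows")
        cfg = ClassifierConfig(
            n_eeg_channels=train_parts[0].eeg.n_channels,
            conv1_out=self.conv1_out,
            dropout=self.dropout,
            max_steps=self.max_steps,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
        )
        self.model = ConvClassifier(cfg, seed=seed)
        train_classifier(self.model, pairs, seed=seed)
        self.fold_artifacts = {
            "stop_step": self.model.stop_step,
            "final_loss": self.model.loss_history[-1],
            "n_pairs": len(pairs),
        }
        return self

    def evaluate_part(self, part: Part, seed: int = 0) -> list[WindowDecision]:
        eeg = _scaled_eeg(self.eeg_scaler, part)
        att = self.env_scaler.transform(part.env_attended.values)
        unatt = self.env_scaler.transform(part.env_unattended.values)
        rng = np.random.default_rng(seed)
        decisions = []
        for i, (s, e) in enumerate(make_windows(part)):
            score_att, score_unatt, _ = classify_window(
                self.model, eeg[:, s:e], att[s:e], unatt[s:e],
                rng=rng, n_draws=self.test_draws,
            )
            decisions.append(WindowDecision(
                part_id=part.part_id, window_index=i,
                score_attended=score_att, score_unattended=score_unatt,
                correct=score_att > score_unatt,
            ))
        return decisions
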