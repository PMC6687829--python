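import numpy as np
import pytest

from aad.nnet.classifier import (ClassifierConfig, ConvClassifier,
                                 LabelledWindow, build_classifier,
                                 classify_window, conv1_channel_importance,
                                 make_training_pairs, random_downsample,
                                 train_classifier)


def separable_pairs(rng, n_windows=12, n_eeg=2, noise=0.05):
    """EEG rows equal to the attended envelope (plus small noise):
    the attended/unattended distinction is trivially learnable."""
    pairs = []
    for i in range(n_windows):
        att = rng.standard_normal(1000)
        unatt = rng.standard_normal(1000)
        eeg = np.tile(att, (n_eeg, 1)) + noise * rng.standard_normal((n_eeg, 1000))
        for env, label in ((att, 1), (unatt, 0)):
            pairs.append(LabelledWindow(
                np.vstack([eeg, env[None, :]]), label, f"p{i}", i))
    return pairs


class TestRandomDownsample:
    def test_shape_and_ordering(self, rng):
        out = random_downsample(rng.standard_normal((5, 1000)), rng=0)
        assert out.shape == (5, 250)

    def test_indices_shared_and_sorted(self):
        base = np.tile(np.arange(1000.0), (3, 1))
        out = random_downsample(base, rng=42)
        assert np.all(np.diff(out[0]) > 0)          # strictly increasing
        assert np.array_equal(out[0], out[1])       # same indices per channel

    def test_seed_reproducible(self, rng):
        x = rng.standard_normal((2, 1000))
        assert np.array_equal(random_downsample(x, rng=7),
                              random_downsample(x, rng=7))

    def test_uniform_selection_frequency(self):
        hits = np.zeros(1000)
        g = np.random.default_rng(0)
        base = np.arange(1000.0)[None, :]
        n_draws = 10000
        for _ in range(n_draws):
            idx = random_downsample(base, rng=g)[0].astype(int)
            hits[idx] += 1
        freq = hits / n_draws
        assert np.all(np.abs(freq - 0.25) < 0.02)

    def test_indivisible_length(self):
        with pytest.raises(ValueError, match="divisible"):
            random_downsample(np.zeros((1, 1001)))


class TestArchitecture:
    def test_wet_conv1_shape(self):
        model = build_classifier(ClassifierConfig(n_eeg_channels=64))
        assert model.conv1.W.value.shape == (64, 65, 3)

    @pytest.mark.parametrize("n_eeg,conv1_out", [(64, 64), (18, 19), (7, 7)])
    def test_flattened_is_246_for_any_montage(self, n_eeg, conv1_out):
        cfg = ClassifierConfig(n_eeg_channels=n_eeg)
        assert cfg.conv1_out == conv1_out
        assert cfg.flattened == 246

    def test_forward_returns_finite_scalars(self, rng):
        model = build_classifier(ClassifierConfig(n_eeg_channels=4), seed=0)
        scores = model.score(rng.standard_normal((6, 5, 250)))
        assert scores.shape == (6,)
        assert np.all(np.isfinite(scores))

    def test_wrong_input_length_rejected(self, rng):
        model = build_classifier(ClassifierConfig(n_eeg_channels=4), seed=0)
        with pytest.raises(ValueError, match="250"):
            model.score(rng.standard_normal((2, 5, 300)))

    def test_gradient_reaches_every_parameter(self, rng):
        model = build_classifier(ClassifierConfig(n_eeg_channels=3), seed=0)
        pairs = separable_pairs(rng, n_windows=4, n_eeg=3)
        model.cfg.max_steps = 1
        train_classifier(model, pairs, seed=0)
        for p in model.parameters():
            assert np.any(p.grad != 0), f"dead parameter {p.name}"


class TestTrainingPairs:
    def _triples(self, rng, n=3):
        for i in range(n):
            yield (rng.standard_normal((2, 1000)), rng.standard_normal(1000),
                   rng.standard_normal(1000), f"p{i}", i)

    def test_balanced_expansion(self, rng):
        pairs = make_training_pairs(self._triples(rng, 3))
        assert len(pairs) == 6
        assert sum(p.label for p in pairs) == 3

    def test_window_pair_labels_differ(self, rng):
        pairs = make_training_pairs(self._triples(rng, 2))
        for i in range(0, len(pairs), 2):
            assert pairs[i].label != pairs[i + 1].label

    def test_stream_swap_flips_labels(self, rng):
        triples = list(self._triples(rng, 2))
        swapped = [(e, u, a, pid, wi) for e, a, u, pid, wi in triples]
        orig = make_training_pairs(triples)
        flip = make_training_pairs(swapped)
        labels_by_window = lambda ps: [(p.window_index, p.label,
                                        p.window[-1].sum()) for p in ps]
        orig_map = {(wi, round(s, 9)): l for wi, l, s in labels_by_window(orig)}
        for wi, l, s in labels_by_window(flip):
            assert orig_map[(wi, round(s, 9))] == 1 - l


class TestTrainingContract:
    def test_separable_task_stops_early(self, rng):
        model = build_classifier(ClassifierConfig(n_eeg_channels=2,
                                                  max_steps=600), seed=0)
        train_classifier(model, separable_pairs(rng), seed=0)
        assert model.stop_step < 600
        assert model.loss_history[-1] < 0.09

    def test_stop_step_is_first_below_threshold(self, rng):
        model = build_classifier(ClassifierConfig(n_eeg_channels=2,
                                                  max_steps=600), seed=0)
        train_classifier(model, separable_pairs(rng), seed=0)
        hist = np.array(model.loss_history)
        first = int(np.flatnonzero(hist < 0.09)[0]) + 1
        assert model.stop_step == first

    def test_max_steps_respected_on_hard_task(self, rng):
        # pure-noise task: loss hovers near log(2), never below 0.09
        pairs = []
        for i in range(6):
            eeg = rng.standard_normal((2, 1000))
            for label in (1, 0):
                pairs.append(LabelledWindow(
                    np.vstack([eeg, rng.standard_normal((1, 1000))]),
                    label, f"p{i}", i))
        model = build_classifier(ClassifierConfig(n_eeg_channels=2,
                                                  max_steps=25), seed=0)
        train_classifier(model, pairs, seed=0)
        assert model.stop_step == 25
        assert len(model.loss_history) == 25

    def test_seeded_training_bit_identical(self, rng):
        pairs = separable_pairs(rng, n_windows=6)
        runs = []
        for _ in range(2):
            model = build_classifier(ClassifierConfig(n_eeg_channels=2,
                                                      max_steps=30), seed=9)
            train_classifier(model, pairs, seed=9)
            runs.append(model)
        assert runs[0].loss_history == runs[1].loss_history
        for pa, pb in zip(runs[0].parameters(), runs[1].parameters()):
            assert np.array_equal(pa.value, pb.value)

    def test_needs_both_classes(self, rng):
        pairs = [p for p in separable_pairs(rng, 3) if p.label == 1]
        model = build_classifier(ClassifierConfig(n_eeg_channels=2), seed=0)
        with pytest.raises(ValueError, match="positive and one negative"):
            train_classifier(model, pairs, seed=0)


class TestClassifyWindow:
    def _trained(self, rng, **kwargs):
        model = build_classifier(ClassifierConfig(n_eeg_channels=2,
                                                  max_steps=400), seed=0)
        train_classifier(model, separable_pairs(rng, n_windows=16), seed=0)
        return model

    def test_identical_candidates_tie(self, rng):
        model = build_classifier(ClassifierConfig(n_eeg_channels=2), seed=0)
        eeg = rng.standard_normal((2, 1000))
        env = rng.standard_normal(1000)
        with pytest.warns(UserWarning, match="tied"):
            sa, sb, decision = classify_window(model, eeg, env, env, rng=0)
        assert sa == sb
        assert decision == 0

    def test_separable_heldout_accuracy(self, rng):
        model = self._trained(rng)
        correct = 0
        for i in range(20):
            att = rng.standard_normal(1000)
            unatt = rng.standard_normal(1000)
            eeg = np.tile(att, (2, 1)) + 0.05 * rng.standard_normal((2, 1000))
            _, _, decision = classify_window(model, eeg, att, unatt, rng=i)
            correct += decision == 0
        assert correct / 20 > 0.9

    def test_candidate_order_symmetry(self, rng):
        model = self._trained(rng)
        att = rng.standard_normal(1000)
        unatt = rng.standard_normal(1000)
        eeg = np.tile(att, (2, 1))
        sa, sb, d1 = classify_window(model, eeg, att, unatt, rng=3)
        sb2, sa2, d2 = classify_window(model, eeg, unatt, att, rng=3)
        assert sa == pytest.approx(sa2)
        assert sb == pytest.approx(sb2)
        assert d1 == 1 - d2


class TestChannelImportance:
    def _model(self, n_eeg=2):
        return build_classifier(ClassifierConfig(n_eeg_channels=n_eeg), seed=0)

    def test_hand_minmax(self):
        model = self._model(2)
        W = np.zeros_like(model.conv1.W.value)  # (out, in=3, k=3)
        W[0, 0, 1] = -2.0   # abs-sum of middle taps: EEG [2, 6], audio 3
        W[0, 1, 1] = 6.0
        W[0, 2, 1] = 3.0
        model.conv1.W.value = W
        out = conv1_channel_importance(model)
        assert np.allclose(out[:2], [0.0, 1.0])
        assert out[2] == pytest.approx((3.0 - 2.0) / 4.0)

    def test_audio_may_exceed_one(self):
        model = self._model(2)
        W = np.zeros_like(model.conv1.W.value)
        W[0, 0, 1] = 1.0
        W[0, 1, 1] = 2.0
        W[0, 2, 1] = 3.0
        model.conv1.W.value = W
        out = conv1_channel_importance(model)
        assert np.allclose(out[:2], [0.0, 1.0])
        assert out[2] == pytest.approx(2.0)

    def test_degenerate_minmax_warns(self):
        model = self._model(3)
        W = np.zeros_like(model.conv1.W.value)
        W[:, :, 1] = 1.0
        model.conv1.W.value = W
        with pytest.warns(UserWarning, match="degenerate"):
            out = conv1_channel_importance(model)
        assert np.allclose(out, 0.0)

    def test_sums_over_output_channels(self):
        model = self._model(2)
        W = np.zeros_like(model.conv1.W.value)
        W[0, 0, 1] = 1.0
        W[1, 0, 1] = -1.0  # abs values add: channel 0 -> 2
        W[0, 1, 1] = 1.0
        W[0, 2, 1] = 1.5
        model.conv1.W.value = W
        out = conv1_channel_importance(model)
        assert np.allclose(out[:2], [1.0, 0.0])  # eeg raw [2, 1]
        assert out[2] == pytest.approx(0.5)
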