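"""Losses, training loops, model selection, and the CV harness."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import precision_recall_fscore_support

from eegemotion.eeg_network import EEGNetConfig
from eegemotion.nn import Tensor
from eegemotion.preprocessing import EmotionLabel
from eegemotion.synthetic import SyntheticSpec, generate_frame_clips, generate_visual_features
from eegemotion.training import (
    DistillationConfig,
    ablation_suite,
    binary_metrics,
    cross_entropy,
    cross_validate,
    evaluate_eeg,
    grid_search_w,
    l1_feature_loss,
    multitask_loss,
    prepare_bench_data,
    report_band_attention,
    train_eeg_distilled,
    train_visual,
)
from eegemotion.visual_network import VisualNetConfig

QUICK_TRAIN = DistillationConfig(rho=1.0, learning_rate_eeg=3e-3, epochs=6, batch_size=32)
SMALL_NET = EEGNetConfig().small()


@pytest.fixture(scope="module")
def bench_data():
    spec = SyntheticSpec(n_subjects=2, n_trials_per_subject=16, trial_duration=8.0,
                         baseline_duration=2.0, effect_size=3.0, seed=21)
    feats, labels, subjects, _ = prepare_bench_data(spec)
    return feats, labels, subjects


class TestLosses:
    def test_l1_zero_for_identical_sequences(self, rng):
        u = rng.standard_normal((4, 3))
        assert float(l1_feature_loss(u, u.copy()).data) == 0.0

    def test_l1_constant_difference(self, rng):
        u = rng.standard_normal((4, 3))
        assert np.isclose(float(l1_feature_loss(u, u - 0.7, w_star=1.0).data), 0.7)

    def test_l1_matches_double_loop_oracle(self, rng):
        u, v = rng.standard_normal((4, 3)), rng.standard_normal((4, 3))
        acc = 0.0
        for t in range(4):
            for f in range(3):
                acc += abs(u[t, f] - v[t, f])
        acc /= 12.0
        assert np.isclose(float(l1_feature_loss(u, v, w_star=1.3).data), 1.3 * acc)

    def test_l1_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            l1_feature_loss(np.zeros((2, 2)), np.zeros((2, 3)))

    def test_multitask_rho_one_is_exactly_cross_entropy(self, rng):
        probs = rng.dirichlet((1.0, 1.0), size=6)
        y = rng.integers(0, 2, 6)
        vt, vs = rng.standard_normal((6, 3)), rng.standard_normal((6, 3))
        full = float(multitask_loss(probs, y, vt, vs, rho=1.0).data)
        ce = float(cross_entropy(probs, y).data)
        assert full == ce

    def test_multitask_zero_at_perfect_fit(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([0, 1])
        v = np.ones((2, 4))
        assert float(multitask_loss(probs, y, v, v.copy(), rho=0.8).data) == 0.0

    def test_multitask_arithmetic_combination(self):
        # CE = 1 (picked prob e^-1), L1 term = 0.5 -> 0.8*1 + 0.2*0.5 = 0.9
        p = np.exp(-1.0)
        probs = np.array([[p, 1 - p]])
        y = np.array([0])
        vt = np.zeros((1, 4))
        vs = vt - 0.5
        loss = float(multitask_loss(probs, y, vt, vs, rho=0.8, w_star=1.0).data)
        assert np.isclose(loss, 0.9, atol=1e-12)

    def test_zero_probability_is_clamped(self):
        probs = np.array([[0.0, 1.0]])
        loss = float(cross_entropy(probs, np.array([0])).data)
        assert np.isfinite(loss) and loss == pytest.approx(-np.log(1e-12))


class TestBinaryMetrics:
    def test_against_sklearn_oracle(self, rng):
        y_true = rng.integers(0, 2, 60)
        y_pred = rng.integers(0, 2, 60)
        m = binary_metrics(y_true, y_pred)
        p, r, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, pos_label=1, average="binary", zero_division=0.0)
        assert np.isclose(m["precision"], p)
        assert np.isclose(m["recall"], r)
        assert np.isclose(m["f1"], f1)

    def test_f1_harmonic_identity(self, rng):
        for _ in range(20):
            m = binary_metrics(rng.integers(0, 2, 30), rng.integers(0, 2, 30))
            if m["precision"] + m["recall"] > 0:
                expected = 2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"])
                assert np.isclose(m["f1"], expected)


class TestGridSearch:
    def test_default_grid_has_eleven_candidates(self):
        assert len(DistillationConfig().w_grid) == 11
        np.testing.assert_allclose(DistillationConfig().w_grid,
                                   np.round(np.arange(0.5, 1.51, 0.1), 1))

    def test_degenerate_grid_returns_single_value(self):
        cfg = DistillationConfig(w_grid=(0.7,))
        best, scores = grid_search_w(None, None, None, cfg, trainer=lambda w: 0.5)
        assert best == 0.7 and scores == {0.7: 0.5}

    def test_argmax_contract_and_tie_breaking(self):
        cfg = DistillationConfig(w_grid=(0.5, 0.6, 0.7, 0.8))
        preset = {0.5: 0.7, 0.6: 0.9, 0.7: 0.9, 0.8: 0.8}
        best, scores = grid_search_w(None, None, None, cfg, trainer=preset.__getitem__)
        assert best == 0.6  # tie with 0.7 resolves to the smaller w
        assert scores[best] == max(scores.values())


class TestCrossValidate:
    def _data(self, n_per_subject=40, n_subjects=2, seed=0):
        rng = np.random.default_rng(seed)
        n = n_per_subject * n_subjects
        X = rng.standard_normal((n, 4))
        y = np.tile(np.repeat([0, 1], n_per_subject // 2), n_subjects)
        subjects = np.repeat([f"s{i}" for i in range(n_subjects)], n_per_subject)
        return X, y, subjects

    def test_every_sample_tested_once_per_repeat(self):
        X, y, subjects = self._data()
        cfg = DistillationConfig(cv_repeats=2, cv_folds=5)
        tested = {s: [] for s in np.unique(subjects)}

        def fit_predict(xtr, ytr, xte):
            return np.zeros(len(xte), dtype=int)

        result = cross_validate(X, y, subjects, cfg, fit_predict)
        counts = result.fold_metrics.groupby(["subject", "repeat"])["accuracy"].count()
        assert (counts == 5).all()  # 5 folds per repeat per subject

    def test_fit_count_is_repeats_times_folds(self):
        X, y, subjects = self._data()
        cfg = DistillationConfig(cv_repeats=5, cv_folds=10)
        calls = {"n": 0}

        def fit_predict(xtr, ytr, xte):
            calls["n"] += 1
            return np.zeros(len(xte), dtype=int)

        cross_validate(X, y, subjects, cfg, fit_predict)
        assert calls["n"] == 5 * 10 * 2  # 50 fits per subject, 2 subjects

    def test_perfect_classifier_scores_100(self):
        X, y, subjects = self._data()
        lookup = {tuple(x): k for x, k in zip(X, y)}
        cfg = DistillationConfig(cv_repeats=1, cv_folds=4)

        def oracle(xtr, ytr, xte):
            return np.array([lookup[tuple(x)] for x in xte])

        result = cross_validate(X, y, subjects, cfg, oracle)
        for metric in ("accuracy", "precision", "recall", "f1"):
            assert result.mean[metric] == 1.0

    def test_single_class_subject_skipped_with_warning(self):
        X, y, subjects = self._data()
        y = y.copy()
        y[subjects == "s1"] = 0
        cfg = DistillationConfig(cv_repeats=1, cv_folds=4)
        with pytest.warns(UserWarning, match="s1"):
            result = cross_validate(X, y, subjects, cfg,
                                    lambda xtr, ytr, xte: np.zeros(len(xte), dtype=int))
        assert set(result.fold_metrics["subject"]) == {"s0"}


class TestEEGTraining:
    def test_rho_one_identical_to_no_teacher_run(self, bench_data):
        feats, labels, _ = bench_data
        teacher = np.stack(generate_visual_features(labels, feats.shape[1],
                                                    SMALL_NET.lstm_hidden, snr=4.0, seed=0))
        cfg = replace(QUICK_TRAIN, rho=1.0, epochs=2)
        m1, h1 = train_eeg_distilled(feats, labels, teacher, cfg, SMALL_NET, seed=3)
        m2, h2 = train_eeg_distilled(feats, labels, None, cfg, SMALL_NET, seed=3)
        for (k1, p1), (k2, p2) in zip(m1.named_parameters(), m2.named_parameters()):
            assert k1 == k2
            np.testing.assert_array_equal(p1.data, p2.data)
        pd.testing.assert_frame_equal(h1, h2)

    def test_loss_decreases_on_separable_data(self, bench_data):
        feats, labels, _ = bench_data
        _, history = train_eeg_distilled(feats, labels, None, QUICK_TRAIN, SMALL_NET, seed=0)
        assert history["loss"].iloc[-1] < history["loss"].iloc[0]

    def test_misaligned_teacher_rejected(self, bench_data):
        feats, labels, _ = bench_data
        bad = np.zeros((len(labels) - 1, feats.shape[1], SMALL_NET.lstm_hidden))
        with pytest.raises(ValueError):
            train_eeg_distilled(feats, labels, bad, replace(QUICK_TRAIN, rho=0.8),
                                SMALL_NET)

    def test_band_report_shape_and_range(self, bench_data):
        feats, labels, _ = bench_data
        model, _ = train_eeg_distilled(feats[:40], labels[:40], None,
                                       replace(QUICK_TRAIN, epochs=1), SMALL_NET, seed=0)
        report = report_band_attention(model, feats[:40])
        assert list(report) == ["theta", "alpha", "beta", "gamma"]
        assert all(0.0 <= v <= 1.0 for v in report.values())

    def test_band_report_requires_band_attention(self, bench_data):
        feats, labels, _ = bench_data
        cfg = replace(SMALL_NET, band_attention=False)
        model, _ = train_eeg_distilled(feats[:20], labels[:20], None,
                                       replace(QUICK_TRAIN, epochs=1), cfg, seed=0)
        with pytest.raises(ValueError):
            report_band_attention(model, feats[:20])


class TestVisualTraining:
    def _clips(self, n=60, seed=0, t_steps=8):
        labels = [EmotionLabel.from_rating("valence", 8 if k else 2)
                  for k in np.tile([0, 1], n // 2)]
        return generate_frame_clips(labels, t_steps=t_steps, seed=seed)

    def test_loss_decreases_and_best_checkpoint_reproducible(self, tmp_path):
        clips = self._clips(40)
        cfg = DistillationConfig(learning_rate_visual=3e-3, epochs=5, batch_size=16)
        model, history = train_visual(clips, cfg, VisualNetConfig().small(), seed=0)
        assert history["loss"].iloc[-1] < history["loss"].iloc[0]

        from eegemotion.io import read_checkpoint, write_checkpoint
        from eegemotion.visual_network import VisualNet

        frames = np.stack([c.frames for c in clips[:4]])
        ref = model.extract_features(frames)
        write_checkpoint(tmp_path / "v.npz", model)
        clone = VisualNet(VisualNetConfig().small(), seed=99)
        read_checkpoint(tmp_path / "v.npz", clone)
        np.testing.assert_array_equal(clone.extract_features(frames), ref)

    def test_learns_separable_clips(self):
        # 3-seed majority: >= 90% held-out accuracy on high-contrast motion
        clips = self._clips(60)
        cfg = DistillationConfig(learning_rate_visual=3e-3, epochs=30, batch_size=16)
        wins = 0
        for seed in (0, 1, 2):
            model, history = train_visual(clips, cfg, VisualNetConfig().small(), seed=seed)
            if history["val_accuracy"].max() >= 0.9:
                wins += 1
        assert wins >= 2

    def test_empty_clip_list_rejected(self):
        with pytest.raises(ValueError):
            train_visual([], DistillationConfig())


class TestAblationSuite:
    def test_variants_distinct_and_interface(self, bench_data):
        feats, labels, _ = bench_data
        sub = slice(0, 48)
        table = ablation_suite(feats[sub], labels[sub],
                               config=replace(QUICK_TRAIN, epochs=2), seeds=(0,))
        assert set(table["variant"]) == {"full", "band_only", "self_only", "no_attention"}
        counts = dict(zip(table["variant"], table["n_params"]))
        assert counts["full"] > counts["band_only"] > counts["no_attention"]
        assert counts["full"] > counts["self_only"] > counts["no_attention"]

    def test_raw_input_variant_consumes_raw_grids(self, bench_data, rng):
        feats, labels, _ = bench_data
        sub = slice(0, 32)
        raw = rng.standard_normal((32, feats.shape[1], 1, 9, 9))
        table = ablation_suite(feats[sub], labels[sub], raw_features=raw,
                               config=replace(QUICK_TRAIN, epochs=1), seeds=(0,))
        assert "raw_input" in set(table["variant"])
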