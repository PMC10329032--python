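"""Training loop, cross-validation protocols, metrics, statistics."""

import numpy as np
import pytest

from hdsemg.session import WindowSpec, WindowedDataset
from hdsemg.train_eval import (EvalReport, TrainConfig, annotate_p_value,
                               compute_metrics, crossval_by_repetition,
                               encode_labels, fit_model, positional_similarity,
                               row_normalize, shuffled_split_eval,
                               train_subject, wilcoxon_compare)
from hdsemg.vit import GestureTransformer, ModelConfig


def two_class_dataset(n_per_class=40, seed=0):
    """Linearly separable windows: class differs by channel-mean offset."""
    rng = np.random.default_rng(seed)
    windows, labels, reps = [], [], []
    for c in (0, 1):
        for i in range(n_per_class):
            w = rng.normal(0, 0.05, size=(8, 4, 4)) + (0.5 if c else -0.5)
            windows.append(w)
            labels.append(c)
            reps.append(i % 5 + 1)
    return WindowedDataset(np.stack(windows).astype(np.float32),
                           np.array(labels), np.array(reps),
                           WindowSpec(8, 8, 4, 4))


def tiny_model_config(n_classes=2):
    return ModelConfig(d=16, n_layers=1, n_heads=4, mlp_hidden=16,
                       patch=(4, 4), window=8, n_ch=4, n_cv=4,
                       n_classes=n_classes)


class TestTrainSubject:
    def test_separable_task_reaches_high_train_accuracy(self):
        ds = two_class_dataset()
        model, trace = train_subject(ds, tiny_model_config(),
                                     TrainConfig(epochs=20, batch_size=16,
                                                 lr=1e-3, seed=0))
        pred = model.predict(ds.windows)
        assert np.mean(pred == ds.labels) >= 0.99
        assert trace[-1] <= trace[0]

    def test_identical_seeds_identical_losses(self):
        ds = two_class_dataset()
        cfg = TrainConfig(epochs=3, batch_size=16, seed=5)
        _, t1 = train_subject(ds, tiny_model_config(), cfg)
        _, t2 = train_subject(ds, tiny_model_config(), cfg)
        assert t1 == t2

    def test_out_of_range_labels_rejected(self):
        ds = two_class_dataset()
        ds.labels[0] = 7
        with pytest.raises(ValueError, match="labels"):
            train_subject(ds, tiny_model_config(), TrainConfig(epochs=1))


class TestCrossval:
    def test_each_repetition_tested_once(self):
        ds = two_class_dataset()
        report = crossval_by_repetition(ds, tiny_model_config(),
                                        TrainConfig(epochs=2, batch_size=16,
                                                    lr=1e-3))
        assert len(report.fold_accuracies) == 5

    def test_fold_disjointness(self):
        ds = two_class_dataset()
        for rep in np.unique(ds.repetitions):
            test_ids = set(np.flatnonzero(ds.repetitions == rep))
            train_ids = set(np.flatnonzero(ds.repetitions != rep))
            assert not test_ids & train_ids
            assert test_ids | train_ids == set(range(len(ds)))

    def test_constant_predictor_accuracy_equals_class_share(self):
        """A model collapsed to one class scores that class's window share
        (oracle: direct label counting)."""
        ds = two_class_dataset(n_per_class=30)
        labels, _ = encode_labels(ds.labels)
        model = GestureTransformer(tiny_model_config(), seed=0)
        model.head.weight.data[:] = 0.0
        model.head.bias.data[:] = np.array([10.0, 0.0])  # always class 0
        pred = model.predict(ds.windows)
        acc = np.mean(pred == labels)
        assert acc == pytest.approx(np.mean(labels == 0))

    def test_single_repetition_rejected(self):
        ds = two_class_dataset()
        ds.repetitions[:] = 1
        with pytest.raises(ValueError, match="repetitions"):
            crossval_by_repetition(ds, tiny_model_config(),
                                   TrainConfig(epochs=1))

    def test_accuracy_equals_confusion_trace_ratio(self):
        ds = two_class_dataset()
        report = crossval_by_repetition(ds, tiny_model_config(),
                                        TrainConfig(epochs=2, batch_size=16,
                                                    lr=1e-3))
        counts = report.confusion_counts
        pooled_acc = 100.0 * np.trace(counts) / counts.sum()
        # fold accuracies are per-fold; the pooled figure matches the matrix
        assert counts.sum() == len(ds)
        assert 0 <= pooled_acc <= 100


class TestShuffledSplit:
    def test_fixed_seed_reproducible(self):
        ds = two_class_dataset()
        cfg = TrainConfig(epochs=2, batch_size=16, lr=1e-3, seed=1)
        a = shuffled_split_eval(ds, tiny_model_config(), cfg, 0.8, seed=3)
        b = shuffled_split_eval(ds, tiny_model_config(), cfg, 0.8, seed=3)
        assert a.fold_accuracies == b.fold_accuracies

    def test_train_size_is_rounded_fraction(self):
        ds = two_class_dataset(n_per_class=33)   # 66 windows
        report = shuffled_split_eval(ds, tiny_model_config(),
                                     TrainConfig(epochs=1, batch_size=16),
                                     0.8, seed=0)
        assert report.confusion_counts.sum() == 66 - round(0.8 * 66)

    def test_invalid_fraction_rejected(self):
        ds = two_class_dataset()
        with pytest.raises(ValueError, match="fraction"):
            shuffled_split_eval(ds, tiny_model_config(),
                                TrainConfig(epochs=1), 1.2, seed=0)


class TestMetrics:
    def test_identity_matrix_perfect_scores(self):
        m = compute_metrics(np.eye(4) * 5)
        np.testing.assert_allclose(m["precision"], 1.0)
        np.testing.assert_allclose(m["recall"], 1.0)
        np.testing.assert_allclose(m["f1"], 1.0)
        assert m["mcc"] == pytest.approx(1.0)

    def test_symmetric_confusion_gives_zero_mcc(self):
        m = compute_metrics(np.array([[10, 10], [10, 10]]))
        assert m["mcc"] == pytest.approx(0.0, abs=1e-12)

    def test_three_class_fixture_matches_definitions(self):
        counts = np.array([[5, 2, 0], [1, 6, 1], [0, 3, 7]])
        m = compute_metrics(counts)
        # brute force from the definitional formulas
        for k in range(3):
            tp = counts[k, k]
            fp = counts[:, k].sum() - tp
            fn = counts[k, :].sum() - tp
            prec, rec = tp / (tp + fp), tp / (tp + fn)
            assert m["precision"][k] == pytest.approx(prec)
            assert m["recall"][k] == pytest.approx(rec)
            assert m["f1"][k] == pytest.approx(2 * prec * rec / (prec + rec))

    def test_mcc_matches_sklearn_oracle(self):
        from sklearn.metrics import matthews_corrcoef
        rng = np.random.default_rng(0)
        true = rng.integers(0, 3, 200)
        pred = np.where(rng.random(200) < 0.7, true, rng.integers(0, 3, 200))
        counts = np.zeros((3, 3), dtype=int)
        np.add.at(counts, (true, pred), 1)
        m = compute_metrics(counts)
        assert m["mcc"] == pytest.approx(matthews_corrcoef(true, pred),
                                         abs=1e-12)

    def test_row_normalization(self):
        counts = np.array([[2, 2], [0, 0]])
        normalized = row_normalize(counts)
        np.testing.assert_allclose(normalized[0], [0.5, 0.5])
        np.testing.assert_allclose(normalized[1], [0.0, 0.0])

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            compute_metrics(np.zeros((3, 3)))


class TestWilcoxon:
    @pytest.mark.parametrize("p,stars", [
        (0.5, "ns"), (0.03, "*"), (0.005, "**"), (5e-4, "***"),
        (5e-5, "****"), (0.05, "*"), (1e-4, "****")])
    def test_annotation_bins(self, p, stars):
        assert annotate_p_value(p) == stars

    def test_identical_samples_degenerate(self):
        a = [80.0, 82.0, 85.0, 88.0, 90.0]
        with pytest.warns(UserWarning, match="degenerate"):
            p, stars = wilcoxon_compare(a, a)
        assert stars == "ns" and p == 1.0

    def test_clearly_shifted_samples_significant(self):
        a = np.linspace(80, 90, 12)
        b = a + 5.0
        p, stars = wilcoxon_compare(a, b)
        assert p < 0.05
        assert stars in ("*", "**", "***", "****")

    def test_short_samples_rejected(self):
        with pytest.raises(ValueError, match="5"):
            wilcoxon_compare([1, 2], [3, 4])


class TestPositionalSimilarity:
    def test_diagonal_ones_and_symmetry(self):
        model = GestureTransformer(tiny_model_config(), seed=0)
        sim = positional_similarity(model)
        n = model.config.n_patches
        assert sim.shape == (n, n)
        np.testing.assert_allclose(np.diag(sim), 1.0)
        np.testing.assert_allclose(sim, sim.T, atol=1e-12)

    def test_orthogonal_rows_zero_off_diagonal(self):
        pos = np.zeros((3, 4))
        pos[1, 0] = 1.0  # patch row 0
        pos[2, 1] = 2.0  # patch row 1
        sim = positional_similarity(pos)
        assert sim[0, 1] == pytest.approx(0.0)

    def test_zero_norm_row_flagged(self):
        pos = np.zeros((3, 4))
        pos[1, 0] = 1.0
        with pytest.warns(UserWarning, match="zero-norm"):
            sim = positional_similarity(pos)
        assert sim[1, 1] == 0.0


def test_accuracy_decreases_with_activation_overlap():
    """Held-out accuracy falls, on average over seeds, as the gesture
    activation rows are interpolated from disjoint (difficulty 0) to
    identical (difficulty 1)."""
    import warnings

    from hdsemg.nn import using_dtype
    from hdsemg.preprocess import (NormalizationConfig, WindowSpec,
                                   preprocess_session)
    from hdsemg.synth import generate_session, make_separable_benchmark
    from hdsemg.vit import standard_configs

    def accuracy(difficulty, seed):
        spec = make_separable_benchmark(
            4, difficulty, seed=seed, repetition_duration=1.5,
            rest_duration=0.5, n_repetitions=3)
        session, _ = generate_session(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = preprocess_session(session, NormalizationConfig(),
                                    WindowSpec(64, 64, 8, 8),
                                    channel_fraction=0.5)
        cfg = standard_configs("V1", 64, 64, n_classes=4)
        with using_dtype(np.float32):
            report = shuffled_split_eval(
                ds, cfg, TrainConfig(epochs=10, lr=1e-3, seed=seed),
                0.8, seed=seed)
        return report.mean_accuracy

    means = [np.mean([accuracy(d, s) for s in (0, 1)])
             for d in (0.0, 0.5, 1.0)]
    assert means[0] > means[2] + 20.0       # clear separability collapse
    assert means[0] >= means[1] - 2.0       # monotone within noise
    assert means[1] >= means[2] - 2.0


def test_fit_model_annealing_reduces_lr_after_cutoff():
    from hdsemg.nn import annealed_lr
    base = 1e-4
    assert annealed_lr(base, 0, 20, 10) == base
    assert annealed_lr(base, 9, 20, 10) == base
    later = [annealed_lr(base, e, 20, 10) for e in range(10, 20)]
    assert all(later[i + 1] < later[i] for i in range(len(later) - 1))
    assert all(0 < lr < base for lr in later)
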