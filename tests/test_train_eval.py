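"""Metrics, statistics, robustness simulations and the training harness."""

import itertools

import numpy as np
import pytest

from imuhar.augmentation import AugmentationConfig
from imuhar.encoders import EncoderSpec
from imuhar.synthetic_data import Recording
from imuhar.temporal_models import TemporalSpec
from imuhar.train_eval import (
    MovementNet,
    TrainConfig,
    bootstrap_ci,
    compare_modules,
    confusion_matrix,
    crossvalidate,
    evaluate_system,
    make_folds,
    per_class_f1,
    run_experiment_grid,
    sensor_dropout_eval,
    simulate_packet_loss,
    train_system,
    uwaf,
)

SMALL_ENC = EncoderSpec(kind="dense", dense_hidden=(32,), bottleneck_dim=16)
SMALL_TMP = TemporalSpec(kind="dense", input_dim=16, hidden_dim=16)


class TestUwaf:
    def test_perfect_diagonal(self):
        assert uwaf(np.diag([5, 3, 2, 9, 1, 1, 4])) == 1.0

    def test_two_class_hand_case(self):
        conf = np.array([[8, 2], [3, 7]])
        expected = 0.5 * (8 / (8 + 0.5 * (3 + 2)) + 7 / (7 + 0.5 * (2 + 3)))
        assert uwaf(conf) == pytest.approx(expected)

    def test_one_class_fully_missed(self):
        conf = np.diag([4, 4, 4]).astype(float)
        conf[2, 2] = 0
        conf[2, 0] = 4  # class 2 always predicted as class 0
        f1 = per_class_f1(conf)
        assert f1[1] == 1.0 and f1[2] == 0.0
        assert uwaf(conf) == pytest.approx(np.nanmean(f1))

    def test_label_permutation_invariance(self, rng):
        y_true = rng.integers(0, 7, 500)
        y_pred = rng.integers(0, 7, 500)
        base = uwaf(confusion_matrix(y_true, y_pred))
        perm = rng.permutation(7)
        permuted = uwaf(confusion_matrix(perm[y_true], perm[y_pred]))
        assert permuted == pytest.approx(base)

    def test_absent_classes_excluded(self):
        conf = np.zeros((7, 7), dtype=int)
        conf[0, 0] = 10
        conf[1, 1] = 5
        conf[1, 0] = 5
        assert uwaf(conf) == pytest.approx(0.5 * (10 / 12.5 + 5 / 7.5))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            uwaf(np.zeros((7, 7)))


class TestWilcoxon:
    def test_identical_samples_p_near_one(self):
        a = [0.7, 0.72, 0.71, 0.73]
        assert compare_modules(a, a) > 0.8

    def test_symmetric(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 6)
        assert compare_modules(a, b) == pytest.approx(compare_modules(b, a))

    def test_matches_exhaustive_enumeration_small_n(self, rng):
        a = [0.31, 0.55, 0.62]
        b = [0.40, 0.51, 0.90]
        p = compare_modules(a, b)
        # enumeration oracle: rank-sum of sample a over all C(6,3) splits
        pooled = np.array(a + b)
        ranks = pooled.argsort().argsort() + 1
        w_obs = ranks[:3].sum()
        mean_w = ranks.sum() * 3 / 6
        stats = [
            ranks[list(c)].sum() for c in itertools.combinations(range(6), 3)
        ]
        p_exact = np.mean([abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12 for w in stats])
        assert p == pytest.approx(p_exact, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_modules([], [1.0])


class TestBootstrap:
    def test_identical_scores_zero_width(self):
        lo, hi = bootstrap_ci([0.8] * 10, n_iter=200)
        assert lo == hi == pytest.approx(0.8)

    def test_brackets_point_estimate(self, rng):
        scores = rng.normal(0.7, 0.05, 20)
        lo, hi = bootstrap_ci(scores, n_iter=2000, seed=1)
        assert lo <= scores.mean() <= hi

    def test_single_recording_degenerate(self):
        with pytest.warns(UserWarning):
            lo, hi = bootstrap_ci([0.5], n_iter=10)
        assert lo == hi == 0.5

    def test_coverage_on_gaussian_scores(self):
        rng = np.random.default_rng(0)
        hits = 0
        trials = 200
        for _ in range(trials):
            scores = rng.normal(0.7, 0.1, 15)
            lo, hi = bootstrap_ci(scores, n_iter=400, level=0.95, seed=rng)
            hits += lo <= 0.7 <= hi
        # bootstrap percentile CIs undercover slightly at n=15
        assert 0.85 <= hits / trials <= 1.0


class TestPacketLoss:
    def test_rate_zero_identity(self, rng):
        x = rng.normal(size=(24, 400))
        assert np.array_equal(simulate_packet_loss(x, 0.0, rng=rng), x)

    def test_rate_one_zeroes_all(self, rng):
        x = rng.normal(size=(24, 400)) + 1.0
        assert np.all(simulate_packet_loss(x, 1.0, rng=rng) == 0.0)

    def test_fraction_and_burst_alignment(self, rng):
        x = np.ones((24, 40_000))
        out = simulate_packet_loss(x, 0.25, rng=rng)
        for s in range(4):
            block = out[6 * s : 6 * s + 6]
            frac = (block == 0).mean()
            assert abs(frac - 0.25) < 0.01
            # every zero-run length is a multiple of 4
            zero = (block[0] == 0).astype(int)
            edges = np.flatnonzero(np.diff(np.concatenate([[0], zero, [0]])))
            runs = edges[1::2] - edges[::2]
            assert np.all(runs % 4 == 0)

    def test_frame_tensor_variant(self, rng):
        frames = np.ones((50, 24, 120))
        out = simulate_packet_loss(frames, 0.25, rng=rng)
        frac = (out[:, 0:6] == 0).mean()
        assert abs(frac - 0.25) < 0.01


class TestSensorDropoutEval:
    @pytest.fixture(scope="class")
    def trained(self, tiny_dataset):
        model, _ = train_system(
            SMALL_ENC,
            SMALL_TMP,
            tiny_dataset[:3],
            None,
            TrainConfig(max_epochs=2, patience=2, seed=0),
        )
        return model

    def test_combination_counts(self, trained, tiny_dataset):
        _, per1 = sensor_dropout_eval(trained, tiny_dataset[3:], 1)
        _, per2 = sensor_dropout_eval(trained, tiny_dataset[3:], 2)
        assert len(per1) == 4
        assert len(per2) == 6

    def test_zero_dropped_equals_clean(self, trained, tiny_dataset):
        score, per0 = sensor_dropout_eval(trained, tiny_dataset[3:], 0)
        clean = evaluate_system(trained, tiny_dataset[3:]).uwaf
        assert score == pytest.approx(clean)
        assert len(per0) == 1

    def test_dropping_all_rejected(self, trained, tiny_dataset):
        with pytest.raises(ValueError):
            sensor_dropout_eval(trained, tiny_dataset[3:], 4)


class TestFolds:
    def test_partition_contract(self):
        rng = np.random.default_rng(0)
        folds = make_folds(22, 7, rng)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [3, 3, 3, 3, 3, 3, 4]
        union = np.sort(np.concatenate(folds))
        assert np.array_equal(union, np.arange(22))

    def test_too_few_recordings_rejected(self):
        with pytest.raises(ValueError):
            make_folds(5, 7, np.random.default_rng(0))


class TestTraining:
    def test_same_seed_identical_loss_curves(self, tiny_dataset):
        cfg = TrainConfig(max_epochs=3, patience=3, seed=11)
        _, h1 = train_system(SMALL_ENC, SMALL_TMP, tiny_dataset[:2], None, cfg)
        _, h2 = train_system(SMALL_ENC, SMALL_TMP, tiny_dataset[:2], None, cfg)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_patience_terminates_training(self, tiny_dataset):
        # zero learning rate: validation loss can never improve after the
        # first epoch, so training must stop after exactly patience more
        cfg = TrainConfig(lr=0.0, max_epochs=50, patience=3, seed=0)
        _, hist = train_system(SMALL_ENC, SMALL_TMP, tiny_dataset[:2], None, cfg)
        assert hist["epochs_run"] == 1 + cfg.patience
        assert hist["best_epoch"] == 0

    def test_separable_data_reaches_high_training_accuracy(self, tiny_dataset):
        cfg = TrainConfig(max_epochs=25, patience=25, seed=2)
        enc = EncoderSpec(kind="conv2d_si", per_sensor_dim=10)
        tmp = TemporalSpec(kind="dense", input_dim=40, hidden_dim=32)
        model, _ = train_system(enc, tmp, tiny_dataset[:2], None, cfg)
        frames = np.concatenate([r.frames for r in tiny_dataset[:2]])
        labels = np.concatenate([r.labels for r in tiny_dataset[:2]])
        acc = (model.predict(frames) == labels).mean()
        assert acc > 0.95

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty dataset"):
            train_system(SMALL_ENC, SMALL_TMP, [], None, TrainConfig())

    def test_evaluation_is_deterministic(self, tiny_dataset):
        cfg = TrainConfig(max_epochs=2, patience=2, seed=5)
        model, _ = train_system(SMALL_ENC, SMALL_TMP, tiny_dataset[:2], None, cfg)
        a = evaluate_system(model, tiny_dataset[2:])
        b = evaluate_system(model, tiny_dataset[2:])
        assert a.uwaf == b.uwaf
        assert np.array_equal(a.confusion, b.confusion)

    def test_bottleneck_dropout_config_reaches_model(self, tiny_dataset):
        aug = AugmentationConfig.from_keys(["dr2"])
        cfg = TrainConfig(max_epochs=1, patience=1, seed=0)
        model, _ = train_system(SMALL_ENC, SMALL_TMP, tiny_dataset[:2], aug, cfg)
        assert model.bottleneck_dropout.p == pytest.approx(0.3)


class TestCrossValidation:
    def test_partition_and_averaging(self, tiny_dataset):
        cfg = TrainConfig(max_epochs=1, patience=1, n_repeats=2, k_folds=2, seed=1)
        report = crossvalidate(tiny_dataset, SMALL_ENC, SMALL_TMP, None, cfg)
        assert set(report.recording_scores) == {r.recording_id for r in tiny_dataset}
        assert report.uwaf == pytest.approx(np.mean(report.details["repeat_uwafs"]))
        assert report.ci[0] <= report.ci[1]
        # each recording is scored once per repeat
        assert report.confusion.sum() == cfg.n_repeats * sum(
            len(r.labels) for r in tiny_dataset
        )

    def test_too_few_subjects_rejected(self, tiny_dataset):
        cfg = TrainConfig(k_folds=7)
        with pytest.raises(ValueError):
            crossvalidate(tiny_dataset, SMALL_ENC, SMALL_TMP, None, cfg)


class TestExperimentGrids:
    def test_size_complexity_grid(self):
        df = run_experiment_grid("size_complexity")
        assert len(df) == 25 + 3
        sweep = df.dropna(subset=["per_sensor_dim"])
        assert sorted(sweep.per_sensor_dim) == [10, 20, 40]
        assert sweep.loc[sweep.per_sensor_dim == 20, "compression_ratio"].item() == 36.0
        base = df[df.per_sensor_dim.isna()]
        dense = base[(base.encoder == "dense") & (base.temporal == "dense")]
        conv = base[(base.encoder == "conv1d") & (base.temporal == "dense")]
        assert conv.n_parameters.item() < dense.n_parameters.item()

    def test_unknown_experiment_rejected(self):
        with pytest.raises(ValueError):
            run_experiment_grid("bogus")

    def test_robustness_grid_shape(self, tiny_dataset):
        cfg = TrainConfig(max_epochs=1, patience=1, seed=0)
        aug = {"none": AugmentationConfig.none()}
        df = run_experiment_grid(
            "robustness",
            dataset=tiny_dataset,
            cfg=cfg,
            aug_settings=aug,
            packet_repetitions=1,
        )
        # 3 systems x 1 augmentation x 5 conditions
        assert len(df) == 15
        assert set(df.condition) == {
            "clean",
            "sensor_drop1",
            "sensor_drop2",
            "packet_loss25",
            "packet_loss50",
        }
        assert df.config_hash.notna().all()
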