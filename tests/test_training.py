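import numpy as np
import pytest

from rpecg import nn
from rpecg.estimators import ResNetClassifier
from rpecg.training import (
    TrainConfig,
    augment_image,
    compute_pixel_mean,
    evaluate_model,
    kfold_split,
    split_data,
    train_model,
)


class TestSplitData:
    def test_70_15_15_sizes(self):
        split = split_data(range(100), seed=0)
        assert (len(split.train_ids), len(split.val_ids), len(split.test_ids)) == (70, 15, 15)

    def test_same_seed_reproduces(self):
        a = split_data(range(57), seed=4)
        b = split_data(range(57), seed=4)
        assert a.train_ids == b.train_ids
        assert a.val_ids == b.val_ids
        assert a.test_ids == b.test_ids

    def test_partition_exact(self):
        ids = [f"id{i}" for i in range(43)]
        s = split_data(ids, seed=1)
        parts = [set(s.train_ids), set(s.val_ids), set(s.test_ids)]
        assert set().union(*parts) == set(ids)
        assert sum(len(p) for p in parts) == len(ids)

    def test_largest_remainder_rounding(self):
        s = split_data(range(10), seed=0)
        sizes = sorted([len(s.train_ids), len(s.val_ids), len(s.test_ids)])
        assert sum(sizes) == 10
        assert sizes == [1, 2, 7]

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_data(range(10), fractions=(0.5, 0.2, 0.2), seed=0)

    def test_too_few_ids(self):
        with pytest.raises(ValueError):
            split_data([1, 2], seed=0)


class TestKFold:
    def test_five_folds_of_two(self):
        folds = kfold_split(range(10), k=5, seed=0)
        assert len(folds) == 5
        assert all(len(test) == 2 for _, test in folds)

    def test_each_id_tests_exactly_once(self):
        folds = kfold_split(range(23), k=5, seed=3)
        tested = [i for _, test in folds for i in test]
        assert sorted(tested) == list(range(23))

    def test_fold_sizes_differ_by_at_most_one(self):
        folds = kfold_split(range(23), k=5, seed=3)
        sizes = [len(test) for _, test in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_train_test_disjoint(self):
        for train, test in kfold_split(range(20), k=4, seed=1):
            assert not set(train) & set(test)

    def test_k_too_small(self):
        with pytest.raises(ValueError):
            kfold_split(range(10), k=1, seed=0)


class TestPixelMean:
    def test_mean_of_two_images(self):
        a = np.full((4, 4, 3), 1.0)
        m = compute_pixel_mean(np.stack([a, 2 * a]))
        assert np.allclose(m, 1.5)

    def test_centered_training_set_has_zero_mean(self):
        rng = np.random.default_rng(0)
        imgs = rng.random((10, 8, 8, 3))
        m = compute_pixel_mean(imgs)
        assert np.abs((imgs - m).mean(axis=0)).max() < 1e-7

    def test_training_mean_reused_for_test(self, tiny_images):
        X, y = tiny_images
        est = ResNetClassifier(depth=18, base_width=4, input_size=24, epochs=1,
                               batch_size=8, augment=False, seed=0)
        est.fit(X, y)
        held_out = np.zeros((3, 24, 24, 3), dtype=np.float32)
        est.predict(held_out)  # must not recompute the mean from test data
        assert np.allclose(est.pixel_mean_, compute_pixel_mean(
            est.pixel_mean_[None]))  # mean unchanged by prediction

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            compute_pixel_mean(np.zeros((0, 4, 4, 3)))


class TestAugmentation:
    def test_flip_is_involution(self):
        rng = np.random.default_rng(0)
        img = rng.random((16, 16, 3))
        assert np.array_equal(img[:, ::-1][:, ::-1], img)

    def test_identity_when_disabled(self):
        cfg = TrainConfig(horizontal_flip=False, translation_max_px=0,
                          rgb_jitter_sd=0.0)
        img = np.random.default_rng(1).random((16, 16, 3))
        out = augment_image(img, cfg, np.random.default_rng(0))
        assert np.array_equal(out, img)

    def test_outputs_stay_in_unit_interval(self):
        cfg = TrainConfig(translation_max_px=4, rgb_jitter_sd=0.3)
        rng = np.random.default_rng(2)
        img = rng.random((12, 12, 3))
        for _ in range(200):
            out = augment_image(img, cfg, rng)
            assert out.shape == img.shape
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_translation_replicates_edges(self):
        cfg = TrainConfig(horizontal_flip=False, translation_max_px=0,
                          rgb_jitter_sd=0.0)
        img = np.arange(16.0).reshape(4, 4)[:, :, None] / 16
        img = np.repeat(img, 3, axis=2)
        from rpecg.training import _translate_edge_replicate
        out = _translate_edge_replicate(img, 2, 0)
        assert np.array_equal(out[0], img[0])
        assert np.array_equal(out[2], img[0])


def _make_separable(n=30, size=16, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 0.2, size=(n, size, size, 3)).astype(np.float32)
    y = np.arange(n) % 2
    X[y == 1, :size // 2] += 0.7
    return np.clip(X, 0, 1), y


class TestTrainModel:
    def test_reaches_full_accuracy_on_separable_set(self):
        from rpecg.resnet_model import build_network
        X, y = _make_separable(n=30, size=16)
        net = build_network(18, 2, input_size=16, base_width=4, seed=0)
        cfg = TrainConfig(lr_initial=0.05, batch_size=10, max_epochs=20, seed=0,
                          horizontal_flip=False, translation_max_px=0,
                          rgb_jitter_sd=0.0)
        train_model(net, X, y, X[:4], y[:4], cfg, augment=False)
        _, pred = evaluate_model(net, X)
        assert (pred == y).mean() == 1.0

    def test_identical_seed_identical_first_epoch(self):
        from rpecg.resnet_model import build_network
        X, y = _make_separable(n=20, size=16)
        cfg = TrainConfig(batch_size=10, max_epochs=1, seed=5,
                          horizontal_flip=False, translation_max_px=0,
                          rgb_jitter_sd=0.0)
        h1 = train_model(build_network(18, 2, input_size=16, base_width=4, seed=3),
                         X, y, X[:4], y[:4], cfg, augment=False)
        h2 = train_model(build_network(18, 2, input_size=16, base_width=4, seed=3),
                         X, y, X[:4], y[:4], cfg, augment=False)
        assert h1["train_loss"][0] == h2["train_loss"][0]

    def test_plateau_divides_learning_rate(self):
        from rpecg.resnet_model import build_network
        X, y = _make_separable(n=12, size=16)
        # constant (empty-progress) validation: reuse a fixed degenerate set
        # whose error cannot improve -> plateau after `patience` epochs
        X_val = np.zeros((4, 16, 16, 3), dtype=np.float32)
        y_val = np.array([0, 0, 1, 1])
        cfg = TrainConfig(lr_initial=0.1, plateau_patience=2, batch_size=12,
                          max_epochs=6, seed=0, horizontal_flip=False,
                          translation_max_px=0, rgb_jitter_sd=0.0)
        net = build_network(18, 2, input_size=16, base_width=4, seed=0)
        h = train_model(net, X, y, X_val, y_val, cfg, augment=False)
        assert 0.1 in h["lr"] and 0.01 in h["lr"]

    def test_single_class_rejected(self):
        from rpecg.resnet_model import build_network
        X, _ = _make_separable(n=8, size=16)
        net = build_network(18, 2, input_size=16, base_width=4)
        with pytest.raises(ValueError):
            train_model(net, X, np.zeros(8, dtype=int), X, np.zeros(8, dtype=int),
                        TrainConfig(max_epochs=1))

    def test_iteration_schedule_mode(self):
        from rpecg.resnet_model import build_network
        X, y = _make_separable(n=20, size=16)
        cfg = TrainConfig(batch_size=5, max_epochs=2, lr_step_iters=4, seed=0,
                          horizontal_flip=False, translation_max_px=0,
                          rgb_jitter_sd=0.0)
        net = build_network(18, 2, input_size=16, base_width=4)
        h = train_model(net, X, y, X[:4], y[:4], cfg, augment=False)
        # 4 iterations/epoch: lr drops once per epoch
        assert h["lr"] == [0.01, 0.001]


class TestEvaluateModel:
    def test_scores_are_distributions_and_deterministic(self, tiny_images):
        X, y = tiny_images
        est = ResNetClassifier(depth=18, base_width=4, input_size=24, epochs=2,
                               batch_size=8, augment=False, seed=0)
        est.fit(X, y)
        s1 = est.predict_proba(X)
        s2 = est.predict_proba(X)
        assert np.allclose(s1.sum(axis=1), 1.0, atol=1e-6)
        assert np.array_equal(s1, s2)

    def test_argmax_tie_breaks_to_lowest_index(self):
        scores = np.array([[0.4, 0.4, 0.2]])
        assert scores.argmax(axis=1)[0] == 0
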