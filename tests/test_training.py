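import numpy as np
import pytest

from fundcam.data_io import LabelledDataset, Record
from fundcam.training import (EarlyStopper, FocalLossConfig, ReduceLROnPlateau,
                              TrainConfig, class_weights_from_frequencies,
                              early_stopper_step, focal_loss, focal_loss_grad,
                              lr_schedule_step, train_two_stage)


class TestFocalLoss:
    def test_confident_correct_is_zero(self):
        p = np.array([[1.0 - 1e-12]])
        y = np.array([[1]])
        assert focal_loss(p, y) < 1e-9

    def test_gamma_zero_alpha_one_is_cross_entropy(self, rng):
        """The focal factor collapses and plain BCE remains."""
        cfg = FocalLossConfig(gamma=0.0, alpha=1.0)
        for _ in range(100):
            p = rng.uniform(0.01, 0.99, size=(4, 3))
            y = rng.integers(0, 2, size=(4, 3))
            pc = np.where(y == 1, p, 1 - p)
            bce = float(-np.log(pc).mean())
            assert abs(focal_loss(p, y, cfg) - bce) <= 1e-12

    def test_half_probability_hand_value(self):
        """gamma=2, p=0.5: 0.25 * ln 2."""
        loss = focal_loss(np.array([[0.5]]), np.array([[1]]),
                          FocalLossConfig(gamma=2.0, alpha=1.0))
        assert abs(loss - 0.25 * np.log(2.0)) < 1e-12

    def test_strictly_decreasing_in_true_class_probability(self):
        ps = np.linspace(0.05, 0.95, 30)
        losses = [focal_loss(np.array([[p]]), np.array([[1]])) for p in ps]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_doubling_alpha_doubles_contribution(self, rng):
        p = rng.uniform(0.1, 0.9, size=(5, 2))
        y = rng.integers(0, 2, size=(5, 2))
        base = focal_loss(p, y, FocalLossConfig(alpha=np.array([1.0, 1.0])))
        only_0 = focal_loss(p, y, FocalLossConfig(alpha=np.array([1.0, 1e-12])))
        boosted = focal_loss(p, y, FocalLossConfig(alpha=np.array([2.0, 1.0])))
        np.testing.assert_allclose(boosted, base + only_0, rtol=1e-9)

    def test_invalid_probability_raises(self):
        with pytest.raises(ValueError):
            focal_loss(np.array([[1.2]]), np.array([[1]]))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FocalLossConfig(gamma=-1.0)
        with pytest.raises(ValueError):
            FocalLossConfig(alpha=np.array([1.0, -2.0]))

    def test_gradient_matches_finite_difference(self, rng):
        z = rng.normal(0, 2, (3, 4))
        y = rng.integers(0, 2, (3, 4))
        cfg = FocalLossConfig(gamma=2.0, alpha=rng.uniform(0.5, 2.0, 4))
        _, grad = focal_loss_grad(z, y, cfg)
        eps = 1e-6
        for idx in np.ndindex(z.shape):
            zp, zm = z.copy(), z.copy()
            zp[idx] += eps
            zm[idx] -= eps
            fd = (focal_loss_grad(zp, y, cfg)[0] - focal_loss_grad(zm, y, cfg)[0]) / (2 * eps)
            assert abs(fd - grad[idx]) < 1e-7


class TestClassWeights:
    def test_balanced_dataset_all_ones(self):
        labels = np.tile([[1, 0], [0, 1]], (5, 1))
        np.testing.assert_allclose(class_weights_from_frequencies(labels), [1.0, 1.0])

    def test_90_10_imbalance(self):
        labels = np.zeros((100, 2), dtype=int)
        labels[:90, 0] = 1
        labels[:10, 1] = 1
        np.testing.assert_allclose(class_weights_from_frequencies(labels), [0.2, 1.8])

    def test_absent_class_weight_finite(self):
        labels = np.zeros((50, 3), dtype=int)
        labels[:25, 0] = 1
        alpha = class_weights_from_frequencies(labels)
        assert np.isfinite(alpha).all() and abs(alpha.mean() - 1.0) < 1e-12


class TestLRSchedule:
    def test_improving_loss_keeps_lr(self):
        s = ReduceLROnPlateau(lr=1e-4, patience=8)
        for loss in np.linspace(1.0, 0.1, 20):
            assert lr_schedule_step(s, loss) == 1e-4

    def test_three_plateau_cycles_reach_and_clamp_at_floor(self):
        """1e-4 * 0.1^3 = 1e-7 = floor, then no further reduction."""
        s = ReduceLROnPlateau(lr=1e-4, factor=0.1, patience=8, floor=1e-7)
        lr_schedule_step(s, 1.0)  # establishes best
        lrs = [lr_schedule_step(s, 1.0) for _ in range(8 * 5)]
        assert min(lrs) == pytest.approx(1e-7)
        assert lrs[-1] == pytest.approx(1e-7)
        seen = sorted(set(round(float(np.log10(v))) for v in lrs))
        assert seen == [-7, -6, -5, -4]

    def test_floor_already_reached_unchanged(self):
        s = ReduceLROnPlateau(lr=1e-7, factor=0.1, patience=1, floor=1e-7)
        lr_schedule_step(s, 1.0)
        assert lr_schedule_step(s, 2.0) == pytest.approx(1e-7)


class TestEarlyStopper:
    def test_stops_after_20_stale_epochs(self):
        s = EarlyStopper(patience=20)
        assert early_stopper_step(s, 1.0) == (True, True)
        results = [early_stopper_step(s, 1.0) for _ in range(20)]
        assert [r[0] for r in results[:-1]] == [True] * 19
        assert results[-1][0] is False

    def test_improvement_resets_counter(self):
        s = EarlyStopper(patience=20)
        early_stopper_step(s, 1.0)
        for _ in range(19):
            early_stopper_step(s, 1.0)
        go_on, is_best = early_stopper_step(s, 0.5)
        assert go_on and is_best and s.bad_epochs == 0

    def test_monotone_improvement_never_stops(self):
        s = EarlyStopper(patience=20)
        outs = [early_stopper_step(s, loss) for loss in np.linspace(2.0, 0.1, 50)]
        assert all(go for go, _ in outs)
        assert all(best for _, best in outs)


class TestTrainConfig:
    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_floor=1e-3, lr_init=1e-4)
        with pytest.raises(ValueError):
            TrainConfig(lr_factor=1.5)
        with pytest.raises(ValueError):
            TrainConfig(lr_patience_epochs=0)


def _tiny_dataset(n=12, size=32, seed=0):
    from fundcam.synthetic import SyntheticSpec, generate_dataset
    spec = SyntheticSpec(image_size=size, n_classes=2, label_prevalence=0.6,
                         blob_radius=(3.0, 5.0), seed=seed)
    return generate_dataset(spec, n)[0]


class TestTwoStage:
    def test_checkpoint_count_and_manifest_determinism(self):
        """folds x backbones checkpoints; the run manifest is seed-stable."""
        dataset = _tiny_dataset()
        cfg = TrainConfig(epochs=2, batch_size=8, folds=2, seed=11,
                          use_classic_augment=True)
        c1, set1, m1 = train_two_stage(dataset, cfg, backbones=("tiny_cnn",),
                                       input_size=(32, 32))
        assert len(c1) == 2
        c2, set2, m2 = train_two_stage(dataset, cfg, backbones=("tiny_cnn",),
                                       input_size=(32, 32))
        assert m1["fold_assignments"] == m2["fold_assignments"]
        assert m1["record_ids"] == m2["record_ids"]
        assert m1["n_crops"] == m2["n_crops"]
        for a, b in zip(c1[0].state, c2[0].state):
            np.testing.assert_array_equal(a, b)

    def test_too_small_dataset_raises(self):
        dataset = _tiny_dataset(n=3)
        with pytest.raises(ValueError):
            train_two_stage(dataset, TrainConfig(epochs=1, folds=5),
                            backbones=("tiny_cnn",), input_size=(32, 32))
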