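import numpy as np
import pytest

from ecgstress import nn
from ecgstress.dataset import WindowedDataset
from ecgstress.model import (ModelConfig, build_model, he_initialize,
                             predict, save_checkpoint, state_checksums)
from ecgstress.training import (TrainConfig, TrainingError, TransferError,
                                cross_entropy, lr_at_epoch, prepare_transfer,
                                train)


def _toy_dataset(n=128, offset=1.0, seed=0, n_subjects=4):
    """Linearly separable constant-offset windows."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, size=(n, 2560, 1)).astype(np.float32)
    y = rng.integers(0, 2, n)
    x[y == 1] += offset
    subj = np.array([f"T{i % n_subjects}" for i in range(n)])
    return WindowedDataset(x, y, subj, 10)


class TestCrossEntropy:
    def test_perfect_prediction_near_zero(self):
        y = np.array([1, 0, 1])
        assert cross_entropy(y.astype(float), y) < 1e-10

    def test_half_probability_is_ln2(self):
        assert cross_entropy(np.full(8, 0.5), np.array([0, 1] * 4)) == \
            pytest.approx(np.log(2), abs=1e-12)

    def test_hand_evaluated_batch(self):
        # -(ln 0.9 + ln 0.8) / 2
        loss = cross_entropy(np.array([0.9, 0.2]), np.array([1, 0]))
        assert loss == pytest.approx(0.16425, abs=1e-4)

    def test_out_of_range_clipped(self):
        loss = cross_entropy(np.array([0.0, 1.0]), np.array([1, 0]))
        assert np.isfinite(loss)

    def test_explicit_batch_divisor(self):
        h, y = np.array([0.9, 0.2]), np.array([1, 0])
        assert cross_entropy(h, y, m=4) == pytest.approx(
            cross_entropy(h, y) / 2)


class TestSchedule:
    @pytest.mark.parametrize("regime,epoch,expected", [
        ("I", 0, 1e-3), ("I", 4, 1e-3), ("I", 5, 1e-4), ("II", 9, 1e-4),
        ("III", 0, 1e-4), ("III", 9, 1e-5),
    ])
    def test_values(self, regime, epoch, expected):
        cfg = TrainConfig(regime=regime)
        assert lr_at_epoch(cfg, epoch) == pytest.approx(expected)

    def test_exactly_two_plateaus(self):
        cfg = TrainConfig(regime="I")
        lrs = {lr_at_epoch(cfg, e) for e in range(10)}
        assert len(lrs) == 2

    def test_epoch_bounds(self):
        with pytest.raises(ValueError):
            lr_at_epoch(TrainConfig(regime="I"), 10)

    def test_epoch_cap(self):
        with pytest.raises(ValueError, match="capped"):
            TrainConfig(regime="I", max_epochs=12)

    def test_regime_base_lrs(self):
        assert TrainConfig(regime="I").base_lr == 1e-3
        assert TrainConfig(regime="II").base_lr == 1e-3
        assert TrainConfig(regime="III").base_lr == 1e-4

    def test_regime_frozen_defaults(self):
        assert TrainConfig(regime="II").frozen_stages == frozenset()
        assert TrainConfig(regime="III").frozen_stages == \
            frozenset(range(1, 8))


class TestTrain:
    def test_loss_decreases_on_fixed_tiny_batch(self):
        # 50 optimizer steps on one fixed batch reduce the loss
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 2560, 1)).astype(np.float32)
        y = np.array([0, 1] * 4)
        x[y == 1, :, 0] += 0.5
        onehot = np.eye(2)[y]
        net = he_initialize(build_model(ModelConfig(window_s=10)), 0)
        adam = nn.Adam()
        rngd = np.random.default_rng(1)
        losses = []
        for _ in range(50):
            logits = net.forward(x, training=True, rng=rngd)
            p = nn.softmax(logits.astype(np.float64))
            losses.append(cross_entropy(p[:, 1], y))
            net.backward(((p - onehot) / len(y)).astype(np.float32))
            adam.step(net.trainable_parameters(), 1e-3)
        assert losses[-1] < losses[0]

    def test_capacity_on_separable_toy(self):
        ds = _toy_dataset(n=192, offset=1.0)
        net = he_initialize(build_model(ModelConfig(window_s=10)), 0)
        net, log = train(net, ds, TrainConfig(regime="II", seed=0), ds)
        assert max(e.train_acc for e in log.entries) >= 0.99

    def test_determinism_fixed_seed(self):
        ds = _toy_dataset(n=64)
        runs = []
        for _ in range(2):
            net = he_initialize(build_model(ModelConfig(window_s=10)), 3)
            _, log = train(net, ds, TrainConfig(regime="I", seed=3,
                                                max_epochs=2), ds)
            runs.append(log.losses)
        assert runs[0] == runs[1]

    def test_empty_dataset_error(self):
        ds = WindowedDataset(np.zeros((0, 2560, 1)), np.zeros(0, int),
                             np.array([], dtype=str), 10)
        net = build_model(ModelConfig(window_s=10))
        with pytest.raises(TrainingError, match="empty"):
            train(net, ds, TrainConfig(regime="I"), ds)

    def test_selected_epoch_is_best_test_accuracy(self):
        ds = _toy_dataset(n=96)
        net = he_initialize(build_model(ModelConfig(window_s=10)), 1)
        net, log = train(net, ds, TrainConfig(regime="II", seed=1,
                                              max_epochs=3), ds)
        accs = log.test_accuracies
        assert accs[log.selected_epoch] == max(accs)


@pytest.fixture(scope="module")
def checkpoint(tmp_path_factory):
    net = he_initialize(build_model(ModelConfig(window_s=10)), seed=21)
    path = tmp_path_factory.mktemp("ckpt") / "pre.npz"
    save_checkpoint(net, path, regime="I")
    return path


class TestTransfer:
    def test_head_reinitialized_stages_copied(self, checkpoint):
        from ecgstress.model import load_checkpoint
        pre, _ = load_checkpoint(checkpoint)
        net = prepare_transfer(checkpoint, seed=5)
        assert not np.array_equal(net.head.W, pre.head.W)
        np.testing.assert_array_equal(net.stages[4].conv1.W,
                                      pre.stages[4].conv1.W)
        assert net.frozen_stages == frozenset(range(1, 8))

    def test_same_seed_same_head(self, checkpoint):
        a = prepare_transfer(checkpoint, seed=5)
        b = prepare_transfer(checkpoint, seed=5)
        np.testing.assert_array_equal(a.head.W, b.head.W)

    def test_architecture_mismatch(self, checkpoint):
        with pytest.raises(TransferError, match="window_s"):
            prepare_transfer(checkpoint, seed=0,
                             target_cfg=ModelConfig(window_s=30))

    def test_single_update_respects_freezing(self, checkpoint):
        net = prepare_transfer(checkpoint, seed=5)
        net.set_frozen_stages(frozenset(range(1, 8)))
        before = net.state_dict()
        x = np.random.default_rng(0).normal(
            size=(8, 2560, 1)).astype(np.float32)
        y = np.array([0, 1] * 4)
        logits = net.forward(x, training=True,
                             rng=np.random.default_rng(1))
        p = nn.softmax(logits.astype(np.float64))
        net.backward(((p - np.eye(2)[y]) / 8).astype(np.float32),
                     min_stage=8)
        nn.Adam().step(net.trainable_parameters(), 1e-4)
        after = net.state_dict()
        for k in before:
            if k.startswith(tuple(f"stage{i}." for i in range(1, 8))):
                np.testing.assert_array_equal(before[k], after[k])
        assert not np.array_equal(before["stage8.conv1.W"],
                                  after["stage8.conv1.W"])
        assert not np.array_equal(before["head.W"], after["head.W"])

    def test_regime_iii_frozen_bitexact_through_training(self, checkpoint):
        net = prepare_transfer(checkpoint, seed=5)
        pre_sums = state_checksums(net.state_dict())
        ds = _toy_dataset(n=64, offset=1.0)
        net, _ = train(net, ds, TrainConfig(regime="III", seed=0,
                                            max_epochs=2), ds)
        post_sums = state_checksums(net.state_dict())
        frozen_keys = [k for k in pre_sums
                       if k.startswith(tuple(f"stage{i}."
                                             for i in range(1, 8)))]
        assert frozen_keys
        for k in frozen_keys:
            assert pre_sums[k] == post_sums[k], k
        assert pre_sums["head.W"] != post_sums["head.W"]

    def test_regime_iii_requires_prepared_net(self):
        ds = _toy_dataset(n=64)
        net = he_initialize(build_model(ModelConfig(window_s=10)), 0)
        with pytest.raises(TrainingError, match="pretrained"):
            train(net, ds, TrainConfig(regime="III"), ds)
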