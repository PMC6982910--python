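import numpy as np
import pytest

from bruxsense.classify import (
    AdjustmentLevel,
    NetworkConfig,
    REFERENCE_STAGES,
    TrainConfig,
    altitude_of,
    build_network,
    group_split,
    load_checkpoint,
    make_session_blocks,
    predict_level,
    save_checkpoint,
    train,
)
from bruxsense.classify.layers import Bottleneck1d

from oracles import count_network_params


def toy_blocks(n_per_class=12, seed=0, scale=4.0):
    """Tiny linearly separable 3-class blocks (class-dependent offsets)."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for cls in range(3):
        for _ in range(n_per_class):
            block = rng.normal(0.0, 0.3, size=(16, 128))
            block[:11] += scale * (cls - 1)
            xs.append(block)
            ys.append(cls)
    return np.stack(xs), np.asarray(ys)


class TestNetworkConfig:
    def test_reference_rows(self):
        cfg = NetworkConfig()
        assert cfg.stages == REFERENCE_STAGES
        assert cfg.stages[-1][2] == 3  # final output width

    def test_deviating_row_named(self):
        bad = list(REFERENCE_STAGES)
        bad[3] = ("conv", 32, 100, 1)
        with pytest.raises(ValueError, match="row 3"):
            NetworkConfig(stages=tuple(bad))

    def test_bottleneck_recursion_times(self):
        reps = [r[3] for r in REFERENCE_STAGES if r[0] == "bottleneck"]
        assert reps == [6, 6, 6]

    def test_round_trip_dict(self):
        cfg = NetworkConfig(width_divisor=4, seed=3)
        assert NetworkConfig.from_dict(cfg.to_dict()) == cfg


class TestBuildNetwork:
    def test_forward_shape_full_width(self, rng):
        net = build_network(NetworkConfig(seed=0))
        out = net.forward(rng.normal(size=(2, 16, 128)))
        assert out.shape == (2, 3)
        assert np.all(np.isfinite(out))

    def test_forward_shape_any_valid_length(self, rng):
        net = build_network(NetworkConfig(width_divisor=8, seed=0))
        for length in (32, 64, 128, 256):
            out = net.forward(rng.normal(size=(1, 16, length)))
            assert out.shape == (1, 3)

    def test_softmax_sums_to_one(self, rng):
        net = build_network(NetworkConfig(width_divisor=8, seed=0))
        p = net.predict_proba(rng.normal(size=(4, 16, 128)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_residual_identity_path(self, rng):
        block = Bottleneck1d(8, 8, rng)
        for layer in block.body.iter_layers():
            for p in layer.params:
                p[...] = 0.0
        x = rng.normal(size=(2, 8, 16))
        block.set_training(False)
        assert np.allclose(block.forward(x), x)

    @pytest.mark.parametrize("divisor,widths", [
        (1, (32, 64, 128, 256)),
        (4, (8, 16, 32, 64)),
    ])
    def test_parameter_count_closed_form(self, divisor, widths):
        net = build_network(NetworkConfig(width_divisor=divisor))
        want = count_network_params(widths, in_ch=16, n_classes=3,
                                    expansion=4, kernel=3)
        assert net.n_parameters() == want


class TestTrainConfig:
    def test_reference_values(self):
        cfg = TrainConfig()
        assert cfg.momentum == 0.9
        assert cfg.batch_size == 128
        assert (cfg.train_groups, cfg.test_groups) == (80, 20)

    @pytest.mark.parametrize("kw", [
        {"momentum": 1.0}, {"batch_size": 0}, {"learning_rate": -1.0},
    ])
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            TrainConfig(**kw)


class TestGroupSplit:
    def test_disjoint_80_20(self):
        groups = np.repeat(np.arange(10), 3)
        tr, te = group_split(groups, TrainConfig(),
                             np.random.default_rng(0))
        assert set(tr) & set(te) == set()
        assert len(tr) + len(te) == 30
        tr_groups = set(groups[tr])
        te_groups = set(groups[te])
        assert not tr_groups & te_groups
        assert len(tr_groups) == 8 and len(te_groups) == 2


class TestTrain:
    def test_zero_learning_rate_freezes_weights(self):
        x, y = toy_blocks(4)
        net = build_network(NetworkConfig(width_divisor=8, seed=1))
        before = [p.copy() for p in net.model.parameters()]
        train(net, x, y, TrainConfig(batch_size=8, epochs=2, seed=1,
                                     learning_rate=0.0))
        for b, p in zip(before, net.model.parameters()):
            assert np.array_equal(b, p)

    def test_single_class_rejected(self):
        x, _ = toy_blocks(4)
        net = build_network(NetworkConfig(width_divisor=8, seed=1))
        with pytest.raises(ValueError, match="class"):
            train(net, x, np.zeros(len(x), dtype=int))

    def test_learns_toy_separable_set(self):
        x, y = toy_blocks(12, seed=3)
        net = build_network(NetworkConfig(width_divisor=8, seed=3))
        _, hist = train(net, x, y, TrainConfig(batch_size=12, epochs=20,
                                               seed=3, learning_rate=0.05))
        assert hist[-1]["test_acc"] >= 0.9

    def test_loss_trend_over_seeds(self):
        # finite loss, final below initial, in >= 80% of 10 seeded runs
        x, y = toy_blocks(6, seed=0)
        good = 0
        for seed in range(10):
            net = build_network(NetworkConfig(width_divisor=8, seed=seed))
            _, hist = train(net, x, y, TrainConfig(batch_size=9, epochs=6,
                                                   seed=seed))
            losses = [h["train_loss"] for h in hist]
            if np.all(np.isfinite(losses)) and losses[-1] < losses[0]:
                good += 1
        assert good >= 8

    def test_seeded_training_bit_reproducible(self):
        x, y = toy_blocks(4, seed=5)
        outs = []
        for _ in range(2):
            net = build_network(NetworkConfig(width_divisor=8, seed=5))
            train(net, x, y, TrainConfig(batch_size=8, epochs=3, seed=5))
            outs.append([p.copy() for p in net.model.parameters()])
        for a, b in zip(*outs):
            assert np.array_equal(a, b)

    def test_history_records(self):
        x, y = toy_blocks(4)
        net = build_network(NetworkConfig(width_divisor=8, seed=0))
        _, hist = train(net, x, y, TrainConfig(batch_size=8, epochs=3,
                                               seed=0))
        assert len(hist) == 3
        assert {"epoch", "train_loss", "train_acc", "test_loss",
                "test_acc"} <= set(hist[0])


class TestPredictLevel:
    def test_untrained_warns(self, rng):
        net = build_network(NetworkConfig(width_divisor=8, seed=0))
        with pytest.warns(UserWarning, match="untrained"):
            predict_level(net, rng.normal(size=(16, 128)))

    def test_argmax_semantics(self):
        logits = np.array([0.0, 10.0, 0.0])
        assert int(np.argmax(logits)) == 1

    def test_confusion_diagonal_dominant(self, trained_model):
        _, net, std, _ = trained_model
        x, y, _ = make_session_blocks(15, seed=99, standardize=False)
        x = std.transform(x)
        conf = np.zeros((3, 3), dtype=int)
        for block, label in zip(x, y):
            conf[label, predict_level(net, block).level] += 1
        for c in range(3):
            assert conf[c, c] > conf[c].sum() - conf[c, c]


class TestAltitude:
    @pytest.mark.parametrize("level,mm", [(0, -0.5), (1, 0.0), (2, 0.5)])
    def test_mapping(self, level, mm):
        assert altitude_of(level) == mm

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            altitude_of(3)

    def test_adjustment_level_consistency(self):
        with pytest.raises(ValueError):
            AdjustmentLevel(level=0, altitude=0.5)

    def test_tie_breaks_toward_no_change(self, rng):
        # zero the output layer: all logits equal -> level 1 by the tie rule
        net = build_network(NetworkConfig(width_divisor=8, seed=0))
        final = net.model.layers[-1]
        final.w[...] = 0.0
        final.b[...] = 0.0
        net.trained = True
        level = predict_level(net, rng.normal(size=(16, 128)))
        assert level.level == 1
        assert level.altitude == 0.0
        assert level.confidence == pytest.approx(1 / 3)


class TestCheckpoint:
    def test_round_trip(self, tmp_path, rng):
        net = build_network(NetworkConfig(width_divisor=8, seed=2))
        x, y = toy_blocks(4, seed=2)
        train(net, x, y, TrainConfig(batch_size=8, epochs=2, seed=2))
        path = tmp_path / "m.ckpt"
        save_checkpoint(net, path)
        net2, std = load_checkpoint(path)
        assert std is None
        xin = rng.normal(size=(2, 16, 128))
        assert np.allclose(net.forward(xin), net2.forward(xin))
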