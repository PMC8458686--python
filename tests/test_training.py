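"""Label smoothing, augmentation, the LR range test, and the plateau loop."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brightnuc import nn
from brightnuc.architectures import ArchitectureSpec, build
from brightnuc.training import (AUGMENT_OPS, PlateauScheduler, TrainConfig,
                                augment, bce_loss, expand_dataset,
                                lr_range_test, oriented_epoch,
                                simulate_schedule, smooth_labels, train)
from conftest import scene_pairs


class TestSmoothLabels:
    def test_zero_factor_is_identity(self):
        m = np.array([[0, 1], [1, 0]], float)
        assert np.array_equal(smooth_labels(m, 0.0), m)

    @pytest.mark.parametrize("s", [0.05, 0.15, 0.20])
    def test_maps_hard_labels_to_soft_pair(self, s):
        m = np.array([0.0, 1.0])
        out = smooth_labels(m, s)
        assert out == pytest.approx([s, 1 - s])

    def test_all_ones_mask(self):
        assert np.allclose(smooth_labels(np.ones((3, 3)), 0.05), 0.95)

    def test_factor_half_or_more_rejected(self):
        with pytest.raises(ValueError):
            smooth_labels(np.ones(2), 0.5)

    def test_affine_invertible_and_bce_minimized_at_soft_target(self):
        s = 0.2
        soft = smooth_labels(np.array([0.0, 1.0]), s)
        assert np.allclose((soft - s) / (1 - 2 * s), [0, 1])
        # BCE against target 1-s is minimized at p = 1-s
        ps = np.linspace(0.05, 0.95, 181)
        losses = [bce_loss(np.array([p]), np.array([1 - s])) for p in ps]
        assert ps[int(np.argmin(losses))] == pytest.approx(1 - s, abs=0.01)


class TestBCE:
    def test_perfect_prediction_near_zero(self):
        t = np.array([0.0, 1.0, 1.0])
        p = np.clip(t, 1e-7, 1 - 1e-7)
        assert bce_loss(p, t) < 1e-5

    def test_uninformative_prediction_is_ln2(self):
        t = np.array([0.0, 1.0, 0.0, 1.0])
        assert bce_loss(np.full(4, 0.5), t) == pytest.approx(np.log(2), rel=1e-6)

    def test_soft_self_prediction_value(self):
        val = bce_loss(np.array([0.8]), np.array([0.8]))
        expected = -(0.8 * np.log(0.8) + 0.2 * np.log(0.2))
        assert val == pytest.approx(expected, rel=1e-6)
        assert val == pytest.approx(0.5004, abs=1e-4)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros(3), np.zeros(4))


class TestAugment:
    def test_rot90_is_counterclockwise(self):
        img = np.array([[1, 2], [3, 4]])
        out, _ = augment(img, img, "rot90")
        assert np.array_equal(out, [[2, 4], [1, 3]])

    @pytest.mark.parametrize("op", ["hflip", "vflip", "rot180"])
    def test_involutions(self, op, rng):
        img = rng.random((6, 5))
        once, _ = augment(img, img, op)
        twice, _ = augment(once, once, op)
        assert np.array_equal(twice, img)

    def test_rot180_equals_double_rot90(self, rng):
        img = rng.random((6, 6))
        r90, _ = augment(img, img, "rot90")
        r180a, _ = augment(r90, r90, "rot90")
        r180b, _ = augment(img, img, "rot180")
        assert np.array_equal(r180a, r180b)

    @pytest.mark.parametrize("op", AUGMENT_OPS)
    def test_mask_stays_aligned_and_lossless(self, op, rng):
        img = rng.random((8, 8))
        msk = (rng.random((8, 8)) > 0.6).astype(float)
        img2, msk2 = augment(img, msk, op)
        assert msk2.sum() == msk.sum()  # pixel permutation only
        # the foreground pixels carry the same intensity multiset
        assert np.allclose(sorted(img2[msk2 > 0]), sorted(img[msk > 0]))

    def test_unknown_op_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            augment(np.zeros((2, 2)), np.zeros((2, 2)), "rot45")


class TestExpandDataset:
    def test_sixfold_expansion(self, rng):
        pairs = [(rng.random((4, 4)), rng.random((4, 4))) for _ in range(16)]
        epoch = oriented_epoch(pairs, True, np.random.default_rng(0))
        assert len(epoch) == 96

    def test_without_augment_stream_repeats(self, rng):
        pair = (rng.random((4, 4)), rng.random((4, 4)))
        stream = expand_dataset([pair], do_augment=False, seed=0)
        for _ in range(3):
            img, _ = next(stream)
            assert np.array_equal(img, pair[0])

    def test_same_seed_same_order(self, rng):
        pairs = [(np.full((2, 2), i), np.full((2, 2), i)) for i in range(5)]
        a = [next(expand_dataset(pairs, True, seed=3)) for _ in range(1)]
        s1 = expand_dataset(pairs, True, seed=3)
        s2 = expand_dataset(pairs, True, seed=3)
        for _ in range(20):
            x1, _ = next(s1)
            x2, _ = next(s2)
            assert np.array_equal(x1, x2)


class _Bowl(nn.Module):
    """Surrogate model: one scalar logit parameter, convex BCE bowl."""

    def __init__(self, w0=-4.0):
        super().__init__()
        self.w = nn.Parameter(np.array([w0], dtype=np.float32))
        self.spec = None

    def forward_logits(self, x):
        x = np.asarray(x)
        out = np.broadcast_to(self.w.data.reshape(1, 1, 1, 1),
                              x.shape).copy()
        w = self.w
        return nn.Node(out, (w,), lambda g: (np.array([g.sum()],
                                                      dtype=np.float32),))


class _Flat(nn.Module):
    """Zero-gradient model: constant output detached from its parameter."""

    def __init__(self):
        super().__init__()
        self.w = nn.Parameter(np.zeros(1, dtype=np.float32))

    def forward_logits(self, x):
        return nn.Node(np.zeros(np.asarray(x).shape, dtype=np.float32))


def _const_stream(value=1.0, size=16):
    img = np.full((size, size), 0.5, dtype=np.float32)
    msk = np.full((size, size), value, dtype=np.float32)
    while True:
        yield img, msk


class TestLRRangeTest:
    def test_grid_endpoints(self):
        curve = lr_range_test(_Bowl(), _const_stream(), n_steps=50, patch=16)
        assert curve.rates[0] == pytest.approx(1e-10)
        assert curve.rates[-1] == pytest.approx(10.0)

    def test_candidate_strictly_inside_grid_for_bowl(self):
        curve = lr_range_test(_Bowl(), _const_stream(), n_steps=100, patch=16)
        assert curve.rates[0] < curve.candidate < curve.rates[-1]

    def test_flat_loss_tie_breaks_to_smallest_rate(self):
        curve = lr_range_test(_Flat(), _const_stream(), n_steps=30, patch=16)
        assert curve.candidate == pytest.approx(curve.rates[0])

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError):
            lr_range_test(_Bowl(), _const_stream(), n_steps=5)


def brute_force_schedule(vals, pr=10, ps=20, factor=10.0, lr0=1.0, tol=1e-6):
    """Independent re-statement of the plateau rules, counted by hand."""
    best = np.inf
    streak = 0
    lr = lr0
    lrs = []
    stop = None
    for epoch, v in enumerate(vals, 1):
        if v < best - tol:
            best = v
            streak = 0
        else:
            streak += 1
        if streak >= ps:
            lrs.append(lr)
            stop = epoch
            break
        if streak and streak % pr == 0:
            lr = lr / factor
        lrs.append(lr)
    return lrs, stop


class TestPlateauSchedule:
    def test_frozen_sequence_drops_at_11_stops_at_21(self):
        vals = [1.0] * 40
        lrs, stop = simulate_schedule(vals, lr0=1.0)
        assert stop == 21
        assert lrs[9] == 1.0          # epoch 10: streak 9, untouched
        assert lrs[10] == pytest.approx(0.1)   # epoch 11: first reduction
        assert len(lrs) == 21

    def test_improving_sequence_never_triggers(self):
        vals = list(np.linspace(1.0, 0.1, 30))
        lrs, stop = simulate_schedule(vals)
        assert stop is None
        assert all(lr == 1.0 for lr in lrs)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 2.0, allow_nan=False), min_size=1,
                    max_size=60),
           st.integers(2, 6))
    def test_matches_brute_force_oracle(self, vals, pr):
        got = simulate_schedule(vals, patience_reduce=pr, patience_stop=2 * pr)
        want = brute_force_schedule(vals, pr=pr, ps=2 * pr)
        assert got[1] == want[1]
        assert got[0] == pytest.approx(want[0])

    def test_invalid_patience_rejected(self):
        with pytest.raises(ValueError):
            PlateauScheduler(patience_reduce=20, patience_stop=10)


@pytest.fixture(scope="module")
def tiny_setup():
    pairs = scene_pairs(2, seed=11)
    spec = ArchitectureSpec("ppunet", input_size=64, base_filters=8)
    cfg = TrainConfig(learning_rate=1e-3, batch_size=2, patch_size=64,
                      max_epochs=2, steps_per_epoch=10, seed=4)
    return pairs, spec, cfg


class TestTrainLoop:
    def test_history_schema_and_determinism(self, tiny_setup):
        pairs, spec, cfg = tiny_setup
        runs = []
        for _ in range(2):
            net = build(spec, seed=1)
            stream = expand_dataset(pairs, do_augment=False, seed=4)
            _, hist = train(net, stream, pairs, cfg)
            runs.append(hist)
        assert list(runs[0].columns) == ["epoch", "train_loss", "val_loss", "lr"]
        pd.testing.assert_frame_equal(runs[0], runs[1])
        assert np.allclose(runs[0]["train_loss"], runs[1]["train_loss"],
                           atol=1e-6)

    def test_overfits_two_scenes(self, tiny_setup):
        from brightnuc.evaluation import pixel_metrics
        pairs, spec, cfg = tiny_setup
        net = build(spec, seed=1)
        stream = expand_dataset(pairs, do_augment=False, seed=4)
        net, _ = train(net, stream, pairs,
                       cfg.scaled(max_epochs=4, steps_per_epoch=50))
        f1 = np.mean([pixel_metrics(net.predict(img[..., None]) >= 0.5,
                                    msk > 0).f1 for img, msk in pairs])
        assert f1 > 0.9

    def test_best_weights_restored(self, tiny_setup):
        pairs, spec, cfg = tiny_setup
        net = build(spec, seed=2)
        stream = expand_dataset(pairs, do_augment=False, seed=4)
        net, hist = train(net, stream, pairs, cfg)
        # the returned weights reproduce the best recorded validation loss
        from brightnuc.training import _to_nchw
        net.set_training(False)
        imgs = _to_nchw([p[0] for p in pairs[:cfg.val_batches]])
        t = np.stack([(p[1] > 0).astype(np.float32)
                      for p in pairs[:cfg.val_batches]])[:, None]
        val = float(nn.bce_with_logits(net.forward_logits(imgs), t).data)
        assert val == pytest.approx(hist["val_loss"].min(), rel=1e-5)
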