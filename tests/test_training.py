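"""Loss definitions, learning-rate schedule, and the training loop."""

import numpy as np
import pytest

from petkin import network, patlak, phantom, training
from petkin.training import (LossConfig, OptimizerConfig, huber, loss_diff,
                             loss_suv, lr_at, total_loss)


class TestHuber:
    @pytest.mark.parametrize("r, delta, expect", [
        (0.0, 1.0, 0.0),
        (0.5, 1.0, 0.125),      # quadratic branch: r^2/2
        (2.0, 1.0, 1.5),        # linear branch: delta*(|r| - delta/2)
        (-2.0, 1.0, 1.5),
        (0.3, 0.1, 0.1 * (0.3 - 0.05)),
    ])
    def test_values(self, r, delta, expect):
        assert huber(np.array(r), delta) == pytest.approx(expect)

    def test_continuous_first_derivative(self):
        d = 1.0
        eps = 1e-9
        below = (huber(d, 1.0) - huber(d - eps, 1.0)) / eps
        above = (huber(d + eps, 1.0) - huber(d, 1.0)) / eps
        assert below == pytest.approx(above, abs=1e-6)


class TestLossSuv:
    def test_perfect_prediction_is_zero(self, rng):
        x = rng.random((28, 4, 4))
        v, g = loss_suv(x, x)
        assert v == 0.0 and np.all(g == 0.0)

    def test_input_frames_are_masked(self, rng):
        pred = rng.random((28, 4, 4))
        truth = rng.random((28, 4, 4))
        v1, _ = loss_suv(pred, truth)
        pred2 = pred.copy()
        pred2[:22] += rng.random((22, 4, 4))  # perturb non-target frames
        v2, _ = loss_suv(pred2, truth)
        assert v1 == v2

    def test_matches_naive_loop(self, rng):
        pred = 3 * rng.standard_normal((28, 3, 4))
        truth = 3 * rng.standard_normal((28, 3, 4))
        delta = 0.7
        v, _ = loss_suv(pred, truth, LossConfig(huber_delta=delta))
        acc = 0.0
        for t in range(22, 28):
            for i in range(3):
                for j in range(4):
                    r = abs(pred[t, i, j] - truth[t, i, j])
                    acc += 0.5 * r * r if r <= delta else delta * (r - delta / 2)
        assert v == pytest.approx(acc / (6 * 3 * 4), abs=1e-10)


class TestLossDiff:
    def test_prediction_on_patlak_line_is_zero(self, blood, schedule):
        K = 0.03
        mid = schedule.mid_times
        x, cp = patlak.patlak_x(blood, mid)
        pred = (cp * K * x)[:, None, None] * np.ones((1, 2, 2))
        v, g = loss_diff(pred, blood, schedule)
        assert v == pytest.approx(0.0, abs=1e-15)
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_constant_offset_invariance(self, blood, schedule, rng):
        pred = rng.random((28, 2, 2)) + 1.0
        cfg = LossConfig()
        v1, _ = loss_diff(pred, blood, schedule, cfg)
        mid = schedule.mid_times
        _, cp = patlak.patlak_x(blood, mid)
        # add a constant to y on all linear frames: differences unchanged,
        # and the OLS slope is unchanged too
        pred2 = pred.copy()
        pred2[-13:] += 0.37 * cp[-13:, None, None]
        v2, _ = loss_diff(pred2, blood, schedule, cfg)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_matches_naive_loop(self, blood, schedule, rng):
        pred = rng.random((28, 2, 3)) * 3
        ki = rng.random((2, 3)) * 0.05
        delta = 0.9
        cfg = LossConfig(huber_delta=delta)
        v, _ = loss_diff(pred, blood, schedule, cfg, ki_ref=ki)
        idx = np.arange(15, 28)
        mid = schedule.mid_times[idx]
        x, cp = patlak.patlak_x(blood, mid)
        acc = 0.0
        for k in range(12):
            for i in range(2):
                for j in range(3):
                    y1 = pred[idx[k + 1], i, j] / cp[k + 1]
                    y0 = pred[idx[k], i, j] / cp[k]
                    r = abs((y1 - y0) - ki[i, j] * (x[k + 1] - x[k]))
                    acc += 0.5 * r * r if r <= delta else delta * (r - delta / 2)
        assert v == pytest.approx(acc / (13 * 2 * 3), abs=1e-12)

    def test_gradient_matches_finite_differences(self, blood, schedule, rng):
        pred = rng.random((28, 2, 2)) * 2
        ki = rng.random((2, 2)) * 0.05
        v, g = loss_diff(pred, blood, schedule, ki_ref=ki)
        eps = 1e-7
        for _ in range(10):
            t, i, j = rng.integers(15, 28), rng.integers(2), rng.integers(2)
            p1 = pred.copy(); p1[t, i, j] += eps
            p2 = pred.copy(); p2[t, i, j] -= eps
            fd = (loss_diff(p1, blood, schedule, ki_ref=ki)[0]
                  - loss_diff(p2, blood, schedule, ki_ref=ki)[0]) / (2 * eps)
            assert g[t, i, j] == pytest.approx(fd, rel=1e-5, abs=1e-12)


class TestTotalLoss:
    def test_lambda_zero_is_suv_only(self, blood, schedule, rng):
        pred = rng.random((28, 2, 2))
        truth = rng.random((28, 2, 2))
        cfg = LossConfig(lambda_weight=0.0)
        v, _, parts = total_loss(pred, truth, blood, schedule, cfg)
        assert v == parts["loss_suv"]

    def test_weighted_sum(self, blood, schedule, rng):
        pred = rng.random((28, 2, 2))
        truth = rng.random((28, 2, 2))
        cfg2 = LossConfig(lambda_weight=2.0)
        v, _, parts = total_loss(pred, truth, blood, schedule, cfg2)
        assert v == pytest.approx(parts["loss_suv"] + 2 * parts["loss_diff"])

    def test_zero_when_both_terms_zero(self, blood, schedule):
        K = 0.02
        mid = schedule.mid_times
        x, cp = patlak.patlak_x(blood, mid)
        pred = (cp * K * x)[:, None, None] * np.ones((1, 2, 2))
        v, _, _ = total_loss(pred, pred.copy(), blood, schedule)
        assert v == pytest.approx(0.0, abs=1e-15)


class TestLrSchedule:
    def test_exact_decay_steps(self):
        cfg = OptimizerConfig()
        assert lr_at(0, cfg) == 1e-4
        assert lr_at(9999, cfg) == 1e-4
        assert lr_at(10_000, cfg) == pytest.approx(1e-5)
        assert lr_at(20_000, cfg) == pytest.approx(1e-6)
        assert lr_at(10 ** 6, cfg) == 1e-7


@pytest.fixture(scope="module")
def tiny_setup():
    data = phantom.suv_dataset([0], shape=(16, 16))
    blood = data[0]["blood"]
    schedule = data[0]["schedule"]
    spec = network.EncoderSpec(channel_sizes=(4, 4, 4, 4, 4))
    return data, blood, schedule, spec


class TestTrainLoop:
    def _model(self, blood, schedule, spec):
        return network.HybridModel(blood, schedule, encoder_spec=spec,
                                   head_hidden=(8,), grid_dt=0.5, seed=0,
                                   dtype=np.float32)

    def test_zero_iterations_keeps_initialisation(self, tiny_setup):
        data, blood, schedule, spec = tiny_setup
        model = self._model(blood, schedule, spec)
        before = [p.value.copy() for p in model.params()]
        training.train(model, data, n_iterations=0)
        for p, b in zip(model.params(), before):
            np.testing.assert_array_equal(p.value, b)

    def test_loss_decreases_on_single_slice(self, tiny_setup):
        data, blood, schedule, spec = tiny_setup
        model = self._model(blood, schedule, spec)
        hist = training.train(model, data, n_iterations=60)
        assert hist["loss"][-1] < hist["loss"][0]

    def test_same_seed_identical_loss_curves(self, tiny_setup):
        data, blood, schedule, spec = tiny_setup
        h1 = training.train(self._model(blood, schedule, spec), data,
                            n_iterations=8)
        h2 = training.train(self._model(blood, schedule, spec), data,
                            n_iterations=8)
        np.testing.assert_array_equal(h1["loss"], h2["loss"])

    def test_without_model_variant_trains(self, tiny_setup):
        data, blood, schedule, spec = tiny_setup
        model = network.WithoutModelNet(encoder_spec=spec, head_hidden=(8,),
                                        seed=0, dtype=np.float32)
        hist = training.train(model, data, n_iterations=40)
        assert hist["loss"][-1] < hist["loss"][0]

    def test_nonfinite_loss_is_reported_with_iteration(self, tiny_setup):
        data, blood, schedule, spec = tiny_setup
        model = self._model(blood, schedule, spec)
        bad = [dict(data[0])]
        bad[0]["frames"] = data[0]["frames"].copy()
        bad[0]["frames"][25] = np.nan
        with pytest.raises(FloatingPointError, match="iteration 0"):
            training.train(model, bad, n_iterations=1)


class TestGradientClipping:
    def test_clipped_run_stays_finite_and_learns(self, tiny_setup):
        data, blood, schedule, spec = tiny_setup
        model = network.HybridModel(blood, schedule, encoder_spec=spec,
                                    head_hidden=(8,), grid_dt=0.5, seed=0,
                                    dtype=np.float32)
        cfg = OptimizerConfig(clip_norm=1.0, initial_lr=1e-3)
        hist = training.train(model, data, opt_cfg=cfg, n_iterations=40)
        assert np.all(np.isfinite(hist["loss"]))
        assert hist["loss"][-1] < hist["loss"][0]
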