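import math
import warnings

import numpy as np
import pytest

from ddisiam import ModelConfig, TrainConfig
from ddisiam.training import (
    Lookahead,
    RAdam,
    focal_loss,
    focal_loss_grad_logits,
    lookahead_sync,
    mixup_batch,
    one_hot,
    stratified_fold_indices,
    train_kfold,
    train_one_fold,
)

# ---------------------------------------------------------------------------
# Independent oracle transcriptions of the published optimizer algorithms,
# scalar state, plain Python floats.
# ---------------------------------------------------------------------------


def radam_oracle_trajectory(grads, lr=1e-3, b1=0.9, b2=0.999, eps=1e-8, x0=0.0):
    """Scalar rectified-Adam, transcribed step by step from the published
    pseudocode: moments, bias correction, SMA length rho_t, and the
    rectified adaptive step only when rho_t > 4."""
    rho_inf = 2.0 / (1.0 - b2) - 1.0
    m = v = 0.0
    x = x0
    xs = []
    for t, g in enumerate(grads, start=1):
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        m_hat = m / (1 - b1**t)
        rho_t = rho_inf - 2 * t * b2**t / (1 - b2**t)
        if rho_t > 4:
            v_hat = math.sqrt(v / (1 - b2**t))
            r = math.sqrt(
                ((rho_t - 4) * (rho_t - 2) * rho_inf)
                / ((rho_inf - 4) * (rho_inf - 2) * rho_t)
            )
            x = x - lr * r * m_hat / (v_hat + eps)
        else:
            x = x - lr * m_hat
        xs.append(x)
    return xs


def lookahead_oracle_trajectory(inner_steps, step_factor, period, x0=0.0):
    """Scalar LookAhead: fast weights take the given inner updates; every
    `period` steps slow interpolates toward fast and fast resets."""
    fast = slow = x0
    out = []
    for i, delta in enumerate(inner_steps, start=1):
        fast = fast + delta
        if i % period == 0:
            slow = slow + step_factor * (fast - slow)
            fast = slow
        out.append((fast, slow))
    return out


class TestFocalLoss:
    def test_gamma_zero_equals_cross_entropy(self, rng):
        for _ in range(1000):
            n_c = int(rng.integers(2, 6))
            p = rng.dirichlet(np.ones(n_c), size=1)
            t = one_hot([int(rng.integers(0, n_c))], n_c)
            ce = -float(np.log(np.clip((p * t).sum(), 1e-12, 1.0)))
            assert focal_loss(p, t, gamma=0.0) == pytest.approx(ce, abs=1e-12)

    def test_perfect_prediction_has_zero_loss(self):
        p = np.array([[1.0, 0.0, 0.0]])
        t = np.array([[1.0, 0.0, 0.0]])
        assert focal_loss(p, t, gamma=2.0) == 0.0

    def test_hand_value_at_half(self):
        # (1 - 0.5)^2 * ln 2 = 0.25 ln 2
        p = np.array([[0.5, 0.5]])
        t = np.array([[1.0, 0.0]])
        assert focal_loss(p, t, gamma=2.0) == pytest.approx(0.25 * math.log(2), abs=1e-12)

    def test_uniform_predictor_closed_form(self):
        # p_t = 1/C for every sample: FL = (1 - 1/C)^g * ln C
        c, g = 10, 2.0
        p = np.full((7, c), 1.0 / c)
        t = one_hot(np.arange(7) % c, c)
        expected = (1 - 1 / c) ** g * math.log(c)
        assert focal_loss(p, t, g) == pytest.approx(expected, abs=1e-12)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.array([[0.5, 0.5]]), np.array([[1.0, 0.0]]), gamma=-1.0)

    def test_nonnegative_monotone_and_below_cross_entropy(self):
        pts = np.linspace(0.01, 0.99, 50)
        losses = [
            focal_loss(np.array([[p, 1 - p]]), np.array([[1.0, 0.0]]), 2.0)
            for p in pts
        ]
        ces = [
            focal_loss(np.array([[p, 1 - p]]), np.array([[1.0, 0.0]]), 0.0)
            for p in pts
        ]
        assert all(l >= 0 for l in losses)
        assert all(a >= b - 1e-15 for a, b in zip(losses, losses[1:]))  # non-increasing
        assert all(f <= c + 1e-15 for f, c in zip(losses, ces))

    def test_gradient_matches_finite_differences(self, rng):
        from ddisiam.model import softmax

        z = rng.normal(size=(4, 5))
        t = rng.dirichlet(np.ones(5), size=4)
        g = focal_loss_grad_logits(softmax(z), t, 2.0)
        for i in range(4):
            for j in range(5):
                e = np.zeros_like(z)
                e[i, j] = 1e-6
                num = (
                    focal_loss(softmax(z + e), t, 2.0)
                    - focal_loss(softmax(z - e), t, 2.0)
                ) / 2e-6
                assert g[i, j] == pytest.approx(num, abs=1e-7)


class TestMixup:
    def _batches(self, rng, n=6):
        mk = lambda: (
            rng.normal(size=(n, 4, 3)),
            rng.normal(size=(n, 4, 3)),
            one_hot(rng.integers(0, 3, size=n), 3),
        )
        return mk(), mk()

    def test_lambda_one_returns_first_batch(self, rng):
        b1, b2 = self._batches(rng)
        mixed = mixup_batch(b1, b2, 0.5, 0.5, rng, lam=1.0)
        assert np.array_equal(mixed.xa, b1[0])
        assert np.array_equal(mixed.soft_labels, b1[2])

    def test_midpoint_mixing(self, rng):
        b1 = (np.full((2, 1, 3), 2.0), np.full((2, 1, 3), 2.0), one_hot([0, 0], 2))
        b2 = (np.full((2, 1, 3), 4.0), np.full((2, 1, 3), 4.0), one_hot([1, 1], 2))
        mixed = mixup_batch(b1, b2, 0.5, 0.5, rng, lam=0.5)
        assert np.allclose(mixed.xa, 3.0)
        assert np.allclose(mixed.soft_labels, 0.5)

    def test_label_mass_preserved(self, rng):
        b1, b2 = self._batches(rng)
        mixed = mixup_batch(b1, b2, 0.5, 0.5, rng, per_sample=True)
        assert np.allclose(mixed.soft_labels.sum(axis=1), 1.0, atol=1e-12)

    def test_size_mismatch_rejected(self, rng):
        b1, _ = self._batches(rng, n=6)
        _, b2 = self._batches(rng, n=5)
        with pytest.raises(ValueError, match="mismatch"):
            mixup_batch(b1, b2, 0.5, 0.5, rng)

    def test_default_distribution_mean_is_half(self):
        rng = np.random.default_rng(7)
        draws = rng.beta(0.5, 0.5, size=100_000)
        assert abs(draws.mean() - 0.5) < 0.005


class TestRAdam:
    def test_zero_gradients_are_a_fixed_point(self):
        params = {"x": np.array([1.5, -2.0])}
        opt = RAdam(params)
        for _ in range(10):
            opt.step({"x": np.zeros(2)})
        assert np.array_equal(params["x"], [1.5, -2.0])

    def test_constant_gradient_matches_oracle_over_100_steps(self):
        params = {"x": np.array([0.0])}
        opt = RAdam(params, learning_rate=1e-3)
        mine = []
        for _ in range(100):
            opt.step({"x": np.array([1.0])})
            mine.append(params["x"][0])
        oracle = radam_oracle_trajectory([1.0] * 100)
        assert np.allclose(mine, oracle, atol=1e-10)

    def test_random_gradient_matches_oracle(self, rng):
        grads = rng.normal(size=100)
        params = {"x": np.array([0.3])}
        opt = RAdam(params, learning_rate=2e-3)
        mine = []
        for g in grads:
            opt.step({"x": np.array([g])})
            mine.append(params["x"][0])
        oracle = radam_oracle_trajectory(list(grads), lr=2e-3, x0=0.3)
        assert np.allclose(mine, oracle, atol=1e-10)

    def test_early_steps_are_momentum_only(self):
        """With beta2=0.999 the SMA length stays <= 4 through step 4, so
        the first four updates must be exactly -lr * m_hat (no adaptive
        denominator): constant unit gradient moves the parameter by
        exactly lr each step."""
        lr = 1e-3
        params = {"x": np.array([0.0])}
        opt = RAdam(params, learning_rate=lr)
        for t in range(1, 5):
            opt.step({"x": np.array([1.0])})
            assert params["x"][0] == pytest.approx(-lr * t, abs=1e-15)
        opt.step({"x": np.array([1.0])})  # step 5 switches to the adaptive rule
        assert params["x"][0] != pytest.approx(-lr * 5, abs=1e-6)

    def test_non_finite_gradient_names_parameter(self):
        opt = RAdam({"conv1.w": np.zeros(2)})
        with pytest.raises(FloatingPointError, match="conv1.w"):
            opt.step({"conv1.w": np.array([np.nan, 0.0])})


class TestLookahead:
    def test_step_factor_one_copies_fast(self):
        fast = {"x": np.array([2.0])}
        slow = {"x": np.array([0.0])}
        f2, s2 = lookahead_sync(fast, slow, step_factor=1.0, counter=5, period=5)
        assert s2["x"][0] == 2.0 and f2["x"][0] == 2.0

    def test_half_interpolation(self):
        f2, s2 = lookahead_sync(
            {"x": np.array([2.0])}, {"x": np.array([0.0])},
            step_factor=0.5, counter=5, period=5,
        )
        assert s2["x"][0] == 1.0 and f2["x"][0] == 1.0

    def test_no_op_between_sync_points(self):
        f2, s2 = lookahead_sync(
            {"x": np.array([2.0])}, {"x": np.array([0.0])},
            step_factor=0.5, counter=3, period=5,
        )
        assert f2["x"][0] == 2.0 and s2["x"][0] == 0.0

    def test_equal_weights_sync_is_identity(self):
        f2, s2 = lookahead_sync(
            {"x": np.array([1.0])}, {"x": np.array([1.0])},
            step_factor=0.5, counter=5, period=5,
        )
        assert f2["x"][0] == 1.0 and s2["x"][0] == 1.0

    def test_invalid_period_rejected(self):
        with pytest.raises(ValueError):
            lookahead_sync({}, {}, 0.5, 1, period=0)

    def test_wrapper_matches_oracle_over_100_steps(self, rng):
        deltas = rng.normal(scale=0.1, size=100)
        params = {"x": np.array([0.0])}
        la = Lookahead(params, step_factor=0.5, period=5)
        mine = []
        for d in deltas:
            params["x"] += d  # stand-in for an inner optimizer step
            la.after_step()
            mine.append((params["x"][0], la.slow["x"][0]))
        oracle = lookahead_oracle_trajectory(list(deltas), 0.5, 5)
        assert np.allclose(mine, oracle, atol=1e-10)


class TestTrainConfig:
    def test_defaults_match_study_conditions(self):
        cfg = TrainConfig()
        assert cfg.gamma == 2.0
        assert cfg.mixup_alpha == cfg.mixup_beta == 0.5
        assert cfg.k_folds == 5
        assert cfg.lookahead_k == 5 and cfg.lookahead_step == 0.5

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"gamma": -0.1},
            {"mixup_alpha": 0.0},
            {"lookahead_step": 0.0},
            {"lookahead_step": 1.5},
            {"k_folds": 1},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrainConfig(**kwargs)


def separable_two_class_data(rng, n_per_class=40, n_drugs=6):
    """Two planted blobs in profile space, trivially separable."""
    xa = np.clip(
        np.concatenate(
            [
                rng.normal(0.2, 0.05, size=(n_per_class, n_drugs, 3)),
                rng.normal(0.8, 0.05, size=(n_per_class, n_drugs, 3)),
            ]
        ),
        0,
        1,
    )
    xb = xa + rng.normal(0, 0.02, size=xa.shape)
    y = np.repeat([0, 1], n_per_class)
    perm = rng.permutation(len(y))
    return xa[perm], xb[perm], y[perm]


TINY = ModelConfig(conv_channels=(4, 8, 8, 8, 16), mlp_hidden=(16, 8), n_classes=2)
FAST_TRAIN = TrainConfig(epochs=30, batch_size=16, learning_rate=2e-3, seed=0)


class TestTrainOneFold:
    def test_recovers_separable_signal(self, rng):
        """On linearly separable two-class data the network should reach
        at least 0.95 validation accuracy (a nearest-centroid oracle on
        the same data achieves >= 0.99)."""
        xa, xb, y = separable_two_class_data(rng)
        tr, va = np.arange(0, 60), np.arange(60, 80)
        # nearest-centroid oracle bound
        feats = (xa + xb).reshape(len(y), -1)
        cents = np.stack([feats[tr][y[tr] == c].mean(0) for c in (0, 1)])
        d2 = ((feats[va][:, None] - cents[None]) ** 2).sum(-1)
        assert (d2.argmin(1) == y[va]).mean() >= 0.99
        res = train_one_fold(
            (xa[tr], xb[tr], y[tr]), (xa[va], xb[va], y[va]), TINY, FAST_TRAIN
        )
        assert res.report.acc >= 0.95

    def test_same_seed_is_deterministic(self, rng):
        xa, xb, y = separable_two_class_data(rng, n_per_class=15)
        tr, va = np.arange(0, 24), np.arange(24, 30)
        cfg = TrainConfig(epochs=3, batch_size=8, seed=11)
        r1 = train_one_fold((xa[tr], xb[tr], y[tr]), (xa[va], xb[va], y[va]), TINY, cfg)
        r2 = train_one_fold((xa[tr], xb[tr], y[tr]), (xa[va], xb[va], y[va]), TINY, cfg)
        assert r1.report == r2.report
        assert [e["train_loss"] for e in r1.epoch_log] == [
            e["train_loss"] for e in r2.epoch_log
        ]

    def test_warns_on_class_missing_from_training(self, rng):
        xa, xb, y = separable_two_class_data(rng, n_per_class=10)
        cfg = TrainConfig(epochs=1, batch_size=8, seed=0)
        mask0 = y == 0
        with pytest.warns(RuntimeWarning, match="absent from training"):
            train_one_fold(
                (xa[mask0], xb[mask0], y[mask0]), (xa, xb, y), TINY, cfg
            )


class TestTrainKFold:
    def test_folds_partition_and_average(self, rng):
        xa, xb, y = separable_two_class_data(rng, n_per_class=25)
        cfg = TrainConfig(epochs=2, batch_size=16, seed=3, k_folds=5)
        res = train_kfold(xa, xb, y, TINY, cfg)
        assert len(res.fold_results) == 5
        accs = [r.acc for r in res.fold_reports]
        assert res.averaged.acc == pytest.approx(np.mean(accs), abs=1e-12)

    def test_validation_folds_partition_dataset(self):
        y = np.tile(np.arange(4), 10)
        folds = stratified_fold_indices(y, 5, seed=0)
        all_val = np.concatenate([va for _, va in folds])
        assert sorted(all_val) == list(range(len(y)))  # union = dataset
        assert len(all_val) == len(set(all_val))  # pairwise disjoint

    def test_rare_class_stays_in_training_with_warning(self):
        y = np.array([0] * 20 + [1] * 3)
        with pytest.warns(RuntimeWarning, match="fewer than 5"):
            folds = stratified_fold_indices(y, 5, seed=0)
        rare = np.flatnonzero(y == 1)
        for tr, va in folds:
            assert set(rare) <= set(tr)
            assert not set(rare) & set(va)
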