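import numpy as np
import pytest

from rarefynet.model import build_model
from rarefynet.raster_io import PatchTensor, SamplePair, pairs_to_arrays
from rarefynet.training import (
    AdamW,
    OptimizerState,
    TrainConfig,
    TrainingDivergedError,
    _FlatAdamW,
    adamw_step,
    augment_sample,
    hyperparameter_search,
    lr_range_test,
    rmse_loss,
    split_train_test,
    suggest_lr_from_curve,
    train,
)

from conftest import identity_pairs


def make_pair(rng, center_index=0):
    return SamplePair(
        PatchTensor(rng.uniform(0, 1, (3, 3)), rng.uniform(0, 1, (3, 3)),
                    center_index),
        float(rng.uniform(0, 1)),
    )


class TestAugmentation:
    def test_seven_rotations_give_eight_samples(self, rng):
        pair = make_pair(rng)
        out = augment_sample(pair, 7)
        assert len(out) == 8
        for s in out:
            assert s.y == pair.y
            assert s.x.center_index == pair.x.center_index
            assert s.x.patch[1, 1] == pair.x.patch[1, 1]
            assert s.x.locations[1, 1] == pair.x.locations[1, 1]

    def test_ring_multiset_preserved(self, rng):
        pair = make_pair(rng)
        ring = np.sort(np.delete(pair.x.patch.ravel(), 4))
        for s in augment_sample(pair, 7):
            np.testing.assert_array_equal(np.sort(np.delete(s.x.patch.ravel(), 4)),
                                          ring)

    def test_rotations_are_distinct(self, rng):
        out = augment_sample(make_pair(rng), 7)
        flats = {tuple(s.x.patch.ravel()) for s in out}
        assert len(flats) == 8

    def test_eight_steps_is_identity(self, rng):
        from rarefynet.training import _rotate_ring
        grid = rng.uniform(0, 1, (3, 3))
        out = grid
        for _ in range(8):
            out = _rotate_ring(out, 1)
        np.testing.assert_array_equal(out, grid)
        np.testing.assert_array_equal(_rotate_ring(grid, 8), grid)

    def test_rotation_moves_both_layers_together(self, rng):
        pair = make_pair(rng)
        rotated = augment_sample(pair, 1)[1]
        # wherever a patch value moved, its location value moved with it
        for a in range(3):
            for b in range(3):
                src = np.argwhere(pair.x.patch == rotated.x.patch[a, b])
                assert pair.x.locations[tuple(src[0])] == rotated.x.locations[a, b]

    def test_bad_rotation_count_rejected(self, rng):
        with pytest.raises(ValueError):
            augment_sample(make_pair(rng), 8)


class TestRmseLoss:
    def test_zero_iff_equal(self, rng):
        y = rng.uniform(0, 1, 10)
        assert rmse_loss(y, y) == 0.0
        assert rmse_loss(y + 0.1, y) > 0.0

    def test_known_value(self):
        assert rmse_loss(np.array([3.0, 4.0]), np.zeros(2)) == \
            pytest.approx(np.sqrt(12.5))

    def test_positive_homogeneity(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert rmse_loss(b + 3.0 * (a - b), b) == pytest.approx(3.0 * rmse_loss(a, b))

    def test_permutation_invariant(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        perm = rng.permutation(30)
        assert rmse_loss(a[perm], b[perm]) == pytest.approx(rmse_loss(a, b))

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            rmse_loss(np.array([]), np.array([]))


def reference_adam(theta0, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
    """Textbook Adam with bias correction — the independent oracle."""
    theta = theta0.copy()
    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    trajectory = []
    for t, g in enumerate(grads, start=1):
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g ** 2
        m_hat = m / (1 - beta1 ** t)
        v_hat = v / (1 - beta2 ** t)
        theta = theta - lr * m_hat / (np.sqrt(v_hat) + eps)
        trajectory.append(theta.copy())
    return trajectory


class TestAdamW:
    def test_zero_decay_matches_reference_adam(self, rng):
        theta = rng.normal(size=50)
        grads = [rng.normal(size=50) for _ in range(100)]
        oracle = reference_adam(theta, grads, lr=1e-3)
        state = OptimizerState(np.zeros(50), np.zeros(50))
        current = theta.copy()
        for g, expected in zip(grads, oracle):
            current, state = adamw_step(current, g, state, 1e-3, weight_decay=0.0)
            np.testing.assert_allclose(current, expected, atol=1e-10)

    def test_zero_gradient_leaves_pure_decay(self, rng):
        theta = rng.normal(size=10)
        state = OptimizerState(np.zeros(10), np.zeros(10))
        lr, wd = 0.01, 0.5
        new, state = adamw_step(theta, np.zeros(10), state, lr, wd)
        np.testing.assert_allclose(new, theta * (1 - lr * wd), atol=1e-14)

    def test_hand_evaluated_scalar_step(self):
        theta = np.array([1.0])
        new, _ = adamw_step(theta, np.array([1.0]),
                            OptimizerState(np.zeros(1), np.zeros(1)),
                            learning_rate=0.1, weight_decay=0.0)
        # bias-corrected m_hat = v_hat = 1 at t = 1
        assert new[0] == pytest.approx(0.9, abs=1e-8)

    def test_non_finite_gradient_names_parameter(self, rng):
        opt = AdamW({"layer.weight": rng.normal(size=3)}, 1e-3)
        with pytest.raises(FloatingPointError, match="layer.weight"):
            opt.step({"layer.weight": np.array([1.0, np.nan, 0.0])})

    def test_flat_optimizer_matches_per_array_step(self, rng):
        theta = rng.normal(size=40)
        cfg = TrainConfig(learning_rate=2e-3, weight_decay=0.01)
        flat = _FlatAdamW(theta.copy(), cfg)
        state = OptimizerState(np.zeros(40), np.zeros(40))
        expected = theta.copy()
        for _ in range(30):
            g = rng.normal(size=40)
            flat.step(g)
            expected, state = adamw_step(expected, g, state, cfg.learning_rate,
                                         cfg.weight_decay, cfg.beta1, cfg.beta2,
                                         cfg.eps)
            np.testing.assert_allclose(flat.theta, expected, atol=1e-12)


class TestSplit:
    def test_sizes_and_reproducibility(self, rng):
        samples = [make_pair(rng, i) for i in range(100)]
        train_a, test_a = split_train_test(samples, 0.30, seed=4)
        train_b, test_b = split_train_test(samples, 0.30, seed=4)
        assert len(train_a) == 70 and len(test_a) == 30
        assert [p.x.center_index for p in train_a] == \
            [p.x.center_index for p in train_b]
        assert [p.x.center_index for p in test_a] == \
            [p.x.center_index for p in test_b]

    def test_zero_fraction_gives_empty_test(self, rng):
        samples = [make_pair(rng, i) for i in range(10)]
        tr, te = split_train_test(samples, 0.0, seed=0)
        assert te == [] and len(tr) == 10

    def test_union_is_input_multiset(self, rng):
        samples = [make_pair(rng, i) for i in range(37)]
        tr, te = split_train_test(samples, 0.25, seed=1)
        assert sorted(p.x.center_index for p in tr + te) == list(range(37))
        assert not {p.x.center_index for p in tr} & {p.x.center_index for p in te}

    def test_bad_fraction_rejected(self, rng):
        with pytest.raises(ValueError):
            split_train_test([make_pair(rng), make_pair(rng)], 1.0, seed=0)


class TestLrRangeTest:
    def test_quadratic_oracle_bounds_suggestion(self):
        # plain gradient descent on f = c/2 * x^2 diverges for lr > 2/c;
        # simulate the sweep losses in closed form and check the selection
        curvature = 50.0
        lrs = np.geomspace(1e-6, 1.0, 200)
        x = 1.0
        losses = []
        for lr in lrs:
            losses.append(0.5 * curvature * x ** 2)
            x = x * (1 - lr * curvature)
        suggestion, diverged = suggest_lr_from_curve(lrs, np.array(losses))
        assert diverged
        assert suggestion < 2.0 / curvature

    def test_monotone_decrease_falls_back_to_lr_max(self, rng, tiny_arch):
        model = build_model(tiny_arch, seed=0)
        pairs = identity_pairs(rng, 80)
        with pytest.warns(UserWarning, match="never diverged"):
            suggested = lr_range_test(model, pairs, lr_min=1e-9, lr_max=1e-8,
                                      steps=12, batch_size=16)
        assert suggested == pytest.approx(1e-9)

    def test_too_few_steps_rejected(self, rng, tiny_arch):
        with pytest.raises(ValueError, match="10"):
            lr_range_test(build_model(tiny_arch, seed=0),
                          identity_pairs(rng, 20), steps=5)

    def test_suggests_stable_rate_for_real_model(self, rng, tiny_arch):
        model = build_model(tiny_arch, seed=0)
        pairs = identity_pairs(rng, 120)
        lr = lr_range_test(model, pairs, lr_min=1e-6, lr_max=10.0, steps=60,
                           batch_size=32)
        assert 1e-7 < lr < 1.0


class TestTrain:
    def test_identity_task_converges(self, identity_model):
        model, history, test_pairs = identity_model
        assert history["test_loss"].iloc[-1] < 0.02
        assert history["train_loss"].iloc[-1] <= history["train_loss"].iloc[0]
        x, y = pairs_to_arrays(test_pairs)
        assert rmse_loss(model.predict(x), y) < 0.02

    def test_zero_epochs_is_identity(self, rng, tiny_arch):
        model = build_model(tiny_arch, seed=0)
        before = {k: v.copy() for k, v in model.parameters().items()}
        pairs = identity_pairs(rng, 20)
        model, history = train(model, pairs, [], TrainConfig(epochs=0))
        assert history.empty
        for k, v in model.parameters().items():
            np.testing.assert_array_equal(v, before[k])

    def test_deterministic_under_seed(self, rng, tiny_arch):
        pairs = identity_pairs(rng, 40)
        cfg = TrainConfig(epochs=3, seed=11, augmentation_rotations=2)
        runs = []
        for _ in range(2):
            model = build_model(tiny_arch, seed=2)
            _, history = train(model, pairs[:30], pairs[30:], cfg)
            runs.append(history)
        np.testing.assert_array_equal(runs[0]["test_loss"], runs[1]["test_loss"])

    def test_divergence_raises_and_restores_finite_params(self, rng, tiny_arch):
        model = build_model(tiny_arch, seed=0)
        pairs = identity_pairs(rng, 40)
        # AdamW's normalised step is ~learning_rate in magnitude, so only an
        # astronomically large rate pushes float32 activations to overflow
        cfg = TrainConfig(epochs=50, learning_rate=1e30, weight_decay=0.0)
        with pytest.raises(TrainingDivergedError):
            train(model, pairs, [], cfg)
        assert all(np.isfinite(v).all() for v in model.parameters().values())

    def test_empty_training_set_rejected(self, tiny_arch):
        with pytest.raises(ValueError, match="empty"):
            train(build_model(tiny_arch, seed=0), [], [], TrainConfig())


class TestHyperparameterSearch:
    def test_single_config_space_returns_it(self, rng, tiny_arch):
        pairs = identity_pairs(rng, 200)
        cfg = hyperparameter_search({"learning_rate": [3e-4]}, pairs,
                                    budget_random=2, search_epochs=1,
                                    arch_config=tiny_arch, seed=0)
        assert cfg.learning_rate == 3e-4
        assert cfg.epochs == TrainConfig().epochs  # full budget restored

    def test_best_not_worse_than_median(self, rng, tiny_arch):
        pairs = identity_pairs(rng, 300)
        space = {"learning_rate": [1e-5, 5e-4, 5e-2]}
        cfg, trials = hyperparameter_search(space, pairs, budget_random=3,
                                            search_epochs=3, arch_config=tiny_arch,
                                            seed=1, full_output=True)
        assert trials["val_loss"].iloc[0] <= trials["val_loss"].median()
        assert cfg.learning_rate == trials["learning_rate"].iloc[0]

    def test_two_point_space_reproducible(self, rng, tiny_arch):
        pairs = identity_pairs(rng, 200)
        space = {"learning_rate": [1e-2, 5e-4]}
        picks = {hyperparameter_search(space, pairs, budget_random=2,
                                       search_epochs=2, arch_config=tiny_arch,
                                       seed=3).learning_rate
                 for _ in range(2)}
        assert len(picks) == 1

    def test_empty_space_rejected(self, rng):
        with pytest.raises(ValueError):
            hyperparameter_search({}, identity_pairs(rng, 10))
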