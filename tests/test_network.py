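import numpy as np
import pytest

from deepcsd import (
    AdamState,
    ExpressionDataset,
    NetworkParams,
    TrainConfig,
    adam_step,
    backward,
    dropout_mask,
    forward,
    init_params,
    loss,
    one_hot,
    softmax_jacobian,
    train,
)


def _toy_batch(params, n=6, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, params.d_in))
    labels = rng.integers(0, params.n_classes, n)
    Y = np.zeros((n, params.n_classes))
    Y[np.arange(n), labels] = 1.0
    return X, Y


class TestForward:
    def test_zero_network_outputs_uniform_probabilities(self):
        p = NetworkParams(
            W1=np.zeros((5, 10)), theta1=np.zeros(5),
            W2=np.zeros((3, 5)), theta2=np.zeros(3),
            W3=np.zeros((4, 3)), theta3=np.zeros(4),
        )
        probs, _ = forward(np.random.default_rng(0).normal(size=(7, 10)), p)
        np.testing.assert_allclose(probs, 0.25)

    def test_rows_are_probability_vectors(self, toy_params):
        X, _ = _toy_batch(toy_params, n=100, seed=1)
        probs, _ = forward(X, toy_params)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_full_keep_probability_makes_train_equal_eval(self, toy_params):
        toy_params.dropout_keep_p = 1.0
        X, _ = _toy_batch(toy_params)
        p_train, _ = forward(X, toy_params, mode="train", rng=np.random.default_rng(0))
        p_eval, _ = forward(X, toy_params, mode="eval")
        np.testing.assert_array_equal(p_train, p_eval)

    def test_shape_and_finiteness_validation(self, toy_params):
        with pytest.raises(Exception):
            forward(np.zeros((3, 7)), toy_params)
        bad = np.zeros((3, toy_params.d_in))
        bad[0, 0] = np.nan
        with pytest.raises(Exception):
            forward(bad, toy_params)


class TestDropoutMask:
    def test_keep_one_is_all_ones(self):
        mask = dropout_mask((50,), 1.0, np.random.default_rng(0))
        np.testing.assert_array_equal(mask, 1.0)

    def test_zero_fraction_concentrates_at_half(self):
        mask = dropout_mask((10_000,), 0.5, np.random.default_rng(1))
        frac_zero = np.mean(mask == 0)
        sigma = np.sqrt(0.25 / 10_000)
        assert abs(frac_zero - 0.5) < 3 * sigma

    def test_inverted_scaling_is_unbiased(self):
        """E[mask * a] == a over many masks (3 sigma at 10,000 draws)."""
        rng = np.random.default_rng(2)
        a = 1.7
        draws = dropout_mask((10_000,), 0.5, rng) * a
        se = np.std(draws) / 100
        assert abs(draws.mean() - a) < 3 * se

    def test_invalid_keep_probability(self):
        with pytest.raises(ValueError):
            dropout_mask((3,), 0.0, np.random.default_rng(0))

    def test_reproducible_under_fixed_seed(self):
        m1 = dropout_mask((100,), 0.7, np.random.default_rng(5))
        m2 = dropout_mask((100,), 0.7, np.random.default_rng(5))
        np.testing.assert_array_equal(m1, m2)


class TestLoss:
    def test_perfect_predictions_give_zero_loss(self):
        p = _zero_penalty_params()
        Y = np.eye(4)
        lb = loss(Y, Y, p)
        assert lb.total == pytest.approx(0.0, abs=1e-9)

    def test_uniform_predictions_give_ln4(self):
        p = _zero_penalty_params()
        probs = np.full((8, 4), 0.25)
        Y = one_hot(["CMS1", "CMS2", "CMS3", "CMS4"] * 2)
        assert loss(probs, Y, p).data_loss == pytest.approx(np.log(4))

    def test_penalties_match_hand_computed_norms(self):
        p = _zero_penalty_params()
        p.W1 = np.array([[1.0, -2.0], [0.5, 0.0]])
        p.W2 = np.array([[3.0, -1.0]])
        p.l1_coef, p.l2_coef = 0.2, 0.4
        probs = np.full((2, 4), 0.25)
        Y = one_hot(["CMS1", "CMS2"])
        lb = loss(probs, Y, p)
        n = 2
        assert lb.l1_penalty == pytest.approx(0.2 * (3.5 + 4.0) / n)
        assert lb.l2_penalty == pytest.approx(0.5 * 0.4 * (5.25 + 10.0) / n)
        assert lb.total == pytest.approx(lb.data_loss + lb.l1_penalty + lb.l2_penalty)

    def test_zero_probability_at_true_class_is_clipped(self):
        p = _zero_penalty_params()
        probs = np.array([[0.0, 1.0, 0.0, 0.0]])
        Y = one_hot(["CMS1"])
        lb = loss(probs, Y, p)
        assert np.isfinite(lb.total)
        assert lb.data_loss == pytest.approx(-np.log(1e-12))


def _zero_penalty_params():
    return NetworkParams(
        W1=np.zeros((2, 2)), theta1=np.zeros(2),
        W2=np.zeros((1, 2)), theta2=np.zeros(1),
        W3=np.zeros((4, 1)), theta3=np.zeros(4),
    )


class TestSoftmaxJacobian:
    def test_uniform_input_closed_form(self):
        J = softmax_jacobian(np.full(4, 0.25))
        expected = np.full((4, 4), -0.0625)
        np.fill_diagonal(expected, 0.1875)
        np.testing.assert_allclose(J, expected, atol=1e-12)

    def test_one_hot_probability_saturates_to_zero(self):
        np.testing.assert_allclose(
            softmax_jacobian(np.array([1.0, 0, 0, 0])), 0.0, atol=1e-12
        )

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            y = rng.dirichlet(np.ones(4))
            np.testing.assert_allclose(softmax_jacobian(y).sum(axis=1), 0.0, atol=1e-12)

    def test_matches_central_difference_jacobian(self):
        """dsoftmax/dlogits from the closed form vs numeric differentiation."""
        rng = np.random.default_rng(4)
        z = rng.normal(0, 1, 4)

        def softmax(z):
            e = np.exp(z - z.max())
            return e / e.sum()

        y = softmax(z)
        J = softmax_jacobian(y)
        eps = 1e-6
        for k in range(4):
            zp, zm = z.copy(), z.copy()
            zp[k] += eps
            zm[k] -= eps
            num = (softmax(zp) - softmax(zm)) / (2 * eps)
            np.testing.assert_allclose(J[:, k], num, atol=1e-7)


def numeric_gradients(X, Y, params, masks, eps=1e-6):
    """Central finite differences of loss(forward(.)) with frozen masks."""
    grads = {}
    for name in ("W1", "theta1", "W2", "theta2", "W3", "theta3"):
        tensor = getattr(params, name)
        g = np.zeros_like(tensor)
        it = np.nditer(tensor, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = tensor[idx]
            tensor[idx] = orig + eps
            pp, _ = forward(X, params, mode="train", masks=masks)
            lp = loss(pp, Y, params).total
            tensor[idx] = orig - eps
            pm, _ = forward(X, params, mode="train", masks=masks)
            lm = loss(pm, Y, params).total
            tensor[idx] = orig
            g[idx] = (lp - lm) / (2 * eps)
        grads[name] = g
    return grads


class TestBackward:
    def test_analytic_gradients_match_finite_differences(self, toy_params):
        """The central contract: every analytic gradient tensor agrees with
        central differences of the regularized loss, masks frozen."""
        X, Y = _toy_batch(toy_params, n=6, seed=7)
        rng = np.random.default_rng(8)
        masks = (
            dropout_mask((6, 5), toy_params.dropout_keep_p, rng),
            dropout_mask((6, 3), toy_params.dropout_keep_p, rng),
        )
        probs, cache = forward(X, toy_params, mode="train", masks=masks)
        analytic = backward(cache, Y, toy_params)
        numeric = numeric_gradients(X, Y, toy_params, masks)
        for name, ga in analytic.items():
            gn = numeric[name]
            rel = np.abs(ga - gn) / np.maximum(np.abs(ga) + np.abs(gn), 1e-8)
            assert rel.max() < 1e-5, f"{name}: max rel err {rel.max():.2e}"

    def test_eval_mode_gradients_also_match(self, toy_params):
        toy_params.dropout_keep_p = 1.0
        X, Y = _toy_batch(toy_params, n=6, seed=9)
        masks = (np.ones((6, 5)), np.ones((6, 3)))
        _, cache = forward(X, toy_params, mode="train", masks=masks)
        analytic = backward(cache, Y, toy_params)
        numeric = numeric_gradients(X, Y, toy_params, masks)
        for name, ga in analytic.items():
            rel = np.abs(ga - numeric[name]) / np.maximum(
                np.abs(ga) + np.abs(numeric[name]), 1e-8
            )
            assert rel.max() < 1e-5

    def test_true_class_output_row_gradient_points_downhill(self, toy_params):
        """Increasing the true-class W3 row along its input lowers the loss:
        its gradient projection on the cached input is negative."""
        toy_params.l1_coef = toy_params.l2_coef = 0.0
        X, Y = _toy_batch(toy_params, n=1, seed=10)
        masks = (np.ones((1, 5)), np.ones((1, 3)))
        _, cache = forward(X, toy_params, mode="train", masks=masks)
        grads = backward(cache, Y, toy_params)
        t = int(Y[0].argmax())
        assert grads["W3"][t] @ cache["D2"][0] < 0

    def test_saturated_perfect_solution_has_zero_gradient(self):
        params = _zero_penalty_params()
        # logits hugely favouring the true class -> probs one-hot -> zero grad
        params.W3 = np.array([[100.0], [-100.0], [-100.0], [-100.0]])
        X = np.ones((1, 2))
        params.W1 = np.eye(2)
        params.W2 = np.ones((1, 2))
        Y = one_hot(["CMS1"])
        _, cache = forward(X, params, mode="train", masks=(np.ones((1, 2)), np.ones((1, 1))))
        grads = backward(cache, Y, params)
        for g in grads.values():
            np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_cache_params_mismatch_is_error(self, toy_params):
        X, Y = _toy_batch(toy_params)
        _, cache = forward(X, toy_params, mode="eval")
        other = init_params(10, TrainConfig(hidden1=6, hidden2=3), np.random.default_rng(0))
        with pytest.raises(Exception):
            backward(cache, Y, other)


def reference_adam(x0, grad_fn, alpha, beta1, beta2, eps, steps):
    """Textbook Adam, scalar-loop implementation kept independent of the
    package's vectorised version."""
    x = [float(v) for v in x0]
    m = [0.0] * len(x)
    v = [0.0] * len(x)
    traj = []
    for t in range(1, steps + 1):
        g = grad_fn(np.array(x))
        for i in range(len(x)):
            m[i] = beta1 * m[i] + (1 - beta1) * g[i]
            v[i] = beta2 * v[i] + (1 - beta2) * g[i] ** 2
            mhat = m[i] / (1 - beta1**t)
            vhat = v[i] / (1 - beta2**t)
            x[i] -= alpha * mhat / (np.sqrt(vhat) + eps)
        traj.append(list(x))
    return np.array(traj)


class TestAdam:
    def _wrap(self, x0, alpha=0.05):
        params = NetworkParams(
            W1=np.array(x0, dtype=float).reshape(1, -1),
            theta1=np.zeros(1),
            W2=np.zeros((1, 1)), theta2=np.zeros(1),
            W3=np.zeros((4, 1)), theta3=np.zeros(4),
        )
        state = AdamState.for_params(params, alpha=alpha)
        return params, state

    def test_trajectory_matches_reference_on_quadratic(self):
        """100 Adam steps on a quadratic bowl agree with an independent
        implementation to 1e-10."""
        A = np.array([3.0, 1.0, 0.5])
        x0 = np.array([2.0, -3.0, 1.5])
        grad = lambda x: A * x
        ref = reference_adam(x0, grad, alpha=0.05, beta1=0.9, beta2=0.999,
                             eps=1e-8, steps=100)
        params, state = self._wrap(x0)
        traj = []
        for _ in range(100):
            g = {"W1": A * params.W1.ravel()}
            adam_step(params, {"W1": g["W1"].reshape(1, -1)}, state)
            traj.append(params.W1.ravel().copy())
        np.testing.assert_allclose(np.array(traj), ref, atol=1e-10)

    def test_first_step_is_signed_alpha(self):
        x0 = np.array([1.0, -2.0, 3.0])
        params, state = self._wrap(x0, alpha=0.01)
        g = np.array([0.5, -0.2, 0.0])
        adam_step(params, {"W1": g.reshape(1, -1)}, state)
        step = params.W1.ravel() - x0
        np.testing.assert_allclose(step[:2], -0.01 * np.sign(g[:2]), rtol=1e-6)
        assert step[2] == 0.0

    def test_zero_gradient_leaves_parameters_unchanged(self):
        x0 = np.array([1.0, 2.0])
        params, state = self._wrap(x0)
        for _ in range(5):
            adam_step(params, {"W1": np.zeros((1, 2))}, state)
        np.testing.assert_array_equal(params.W1.ravel(), x0)
        assert state.t == 5

    def test_shape_mismatch_is_error(self):
        params, state = self._wrap(np.array([1.0]))
        with pytest.raises(Exception):
            adam_step(params, {"W1": np.zeros((2, 2))}, state)


def _separable_dataset(effect=3.0, seed=0, n_per_class=20, n_genes=24):
    from deepcsd import SimulationConfig, simulate_dataset

    ds, _ = simulate_dataset(
        SimulationConfig(
            n_samples_per_class=(n_per_class,) * 4,
            n_genes=n_genes,
            n_specific_per_pair=4,
            effect_size=effect,
            noise_sd=0.5,
            seed=seed,
        )
    )
    return ds


SMALL_NET = dict(hidden1=32, hidden2=16, batch_size=8)


class TestTrain:
    def test_reaches_full_training_accuracy_on_separable_data(self):
        ds = _separable_dataset()
        cfg = TrainConfig(max_epochs=50, seed=1, **SMALL_NET)
        result = train(ds, cfg)
        assert result.history[-1].train_accuracy == 1.0
        assert len(result.history) <= 50

    def test_same_seed_is_bit_identical(self):
        ds = _separable_dataset(seed=2)
        cfg = TrainConfig(max_epochs=5, seed=3, **SMALL_NET)
        r1 = train(ds, cfg)
        r2 = train(ds, cfg)
        for name in ("W1", "theta1", "W2", "theta2", "W3", "theta3"):
            np.testing.assert_array_equal(
                getattr(r1.params, name), getattr(r2.params, name)
            )

    def test_loss_decreases_over_training(self):
        ds = _separable_dataset(seed=4)
        result = train(ds, TrainConfig(max_epochs=30, seed=5, **SMALL_NET))
        assert result.history[-1].loss.total < result.history[0].loss.total

    def test_missing_class_is_error(self):
        ds = _separable_dataset(seed=6)
        ds.labels = ["CMS1" if l == "CMS2" else l for l in ds.labels]
        with pytest.raises(Exception, match="CMS2"):
            train(ds, TrainConfig(max_epochs=2, **SMALL_NET))

    def test_l2_shrinks_weights_at_convergence(self):
        """Frobenius norm of W1 decreases monotonically as the L2
        coefficient grows on a fixed problem."""
        ds = _separable_dataset(seed=7)
        norms = []
        for coef in (0.0, 1.0, 10.0):
            cfg = TrainConfig(
                max_epochs=40, seed=8, l1_coef=0.0, l2_coef=coef,
                dropout_keep_p=1.0, **SMALL_NET,
            )
            result = train(ds, cfg)
            norms.append(np.linalg.norm(result.params.W1))
        assert norms[0] > norms[1] > norms[2]

    def test_learning_rate_floor_is_honored(self):
        ds = _separable_dataset(seed=9)
        cfg = TrainConfig(
            max_epochs=80, seed=10, lr_patience=1, lr_reduce_factor=0.1,
            min_learning_rate=1e-5, early_stop_patience=200, **SMALL_NET,
        )
        result = train(ds, cfg)
        assert min(r.learning_rate for r in result.history) >= 1e-5
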