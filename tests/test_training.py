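"""Cost, exact backprop (finite-difference oracle), momentum identities and
the training loop."""

import numpy as np
import pytest

import dendrilearn as dl
from dendrilearn.network import block_receptive_field_mask
from dendrilearn.training import Gradients, TrainingDiverged


def scalar_cost_reference(params, outputs, targets, eta, alpha):
    """Straight-line scalar reimplementation of the full cost."""
    a = np.clip(np.atleast_2d(outputs), 1e-12, 1 - 1e-12)
    y = np.atleast_2d(targets)
    data = 0.0
    for m in range(a.shape[0]):
        for j in range(a.shape[1]):
            data -= y[m, j] * np.log(a[m, j]) + (1 - y[m, j]) * np.log(1 - a[m, j])
    data /= a.shape[0]
    w2 = 0.0
    for lw in params.layers:
        for v in lw.W.ravel():
            w2 += v * v
    if params.cross_weights is not None:
        for v in params.cross_weights.ravel():
            w2 += v * v
    return data + alpha / (2 * eta) * w2


def finite_difference_check(params, x, y, amp1, state, crosses=None, h=1e-6):
    """Max error of analytic vs central-difference gradients of the data
    term, holding the field accumulator fixed; relative to the infinity norm
    of each gradient array (central differences carry ~1e-10 absolute
    roundoff noise at h=1e-6, so elementwise ratios on near-zero entries
    measure the oracle, not the gradient)."""
    hp = dl.Hyperparams(eta=1.0)

    def data_cost():
        fp = dl.forward(params, x, state, amp1, crosses=crosses)
        return dl.cost(params, fp.output, y, hp).data_term

    fp = dl.forward(params, x, state, amp1, crosses=crosses)
    g = dl.gradients(params, x, y, fp)
    max_rel = 0.0

    def check_array(W, G, mask=None):
        nonlocal max_rel
        scale = max(np.abs(G).max(), 1e-8)
        for idx in np.ndindex(W.shape):
            if mask is not None and not mask[idx]:
                assert G[idx] == 0.0
                continue
            orig = W[idx]
            W[idx] = orig + h
            cp = data_cost()
            W[idx] = orig - h
            cm = data_cost()
            W[idx] = orig
            fd = (cp - cm) / (2 * h)
            max_rel = max(max_rel, abs(fd - G[idx]) / scale)

    for l, lw in enumerate(params.layers):
        check_array(lw.W, g.dW[l], params.masks[l])
        check_array(lw.b, g.db[l])
    if params.cross_weights is not None:
        check_array(params.cross_weights, g.dW_cross)
    return max_rel


class TestCost:
    def test_perfect_prediction_near_zero(self):
        p = dl.init_network([4, 3, 2], seed=0)
        hp = dl.Hyperparams(eta=0.1, alpha=0.0)
        rep = dl.cost(p, np.array([1.0, 0.0]), np.array([1.0, 0.0]), hp)
        assert rep.data_term < 1e-10
        assert rep.total == rep.data_term

    def test_uniform_half_closed_form(self):
        p = dl.init_network([4, 3, 10], seed=0)
        hp = dl.Hyperparams(eta=0.1, alpha=0.0)
        y = np.zeros(10)
        y[3] = 1.0
        rep = dl.cost(p, np.full(10, 0.5), y, hp)
        assert rep.data_term == pytest.approx(10 * np.log(2), rel=1e-12)

    def test_matches_scalar_reference(self, rng):
        x = rng.standard_normal((8, 6))
        cs = dl.generate_crosses(6, 5, 3, x, seed=1)
        p = dl.init_params("crosses_1h", seed=2, n_inputs=6, n_hidden=3, n_outputs=2, crosses=cs)
        hp = dl.Hyperparams(eta=0.3, alpha=0.01)
        outputs = rng.uniform(0.05, 0.95, size=(4, 2))
        targets = rng.integers(0, 2, size=(4, 2)).astype(float)
        rep = dl.cost(p, outputs, targets, hp)
        ref = scalar_cost_reference(p, outputs, targets, hp.eta, hp.alpha)
        assert rep.total == pytest.approx(ref, abs=1e-12)

    def test_extreme_outputs_clipped(self):
        p = dl.init_network([2, 2, 1], seed=0)
        hp = dl.Hyperparams(eta=0.1)
        rep = dl.cost(p, np.array([0.0]), np.array([1.0]), hp)
        assert np.isfinite(rep.data_term)


class TestGradients:
    @pytest.mark.parametrize("amp1", [0.0, 0.1])
    def test_finite_difference_dense(self, amp1, rng):
        p = dl.init_network([10, 4, 3], seed=4)
        st = p.new_field_state()
        for _ in range(5):  # accumulate history so the subtraction is active
            dl.forward(p, rng.standard_normal(10), st, amp1, training=True)
        x = rng.standard_normal(10)
        y = np.array([0.0, 1.0, 0.0])
        assert finite_difference_check(p, x, y, amp1, st) < 1e-6

    @pytest.mark.parametrize("amp1", [0.0, 0.1])
    def test_finite_difference_masked_tree(self, amp1, rng):
        mask = block_receptive_field_mask(32, 16)
        p = dl.init_network([32, 2, 1], seed=6, masks=[mask, None])
        st = p.new_field_state()
        for _ in range(5):
            dl.forward(p, rng.standard_normal(32), st, amp1, training=True)
        x = rng.standard_normal(32)
        y = np.array([1.0])
        assert finite_difference_check(p, x, y, amp1, st) < 1e-6

    def test_finite_difference_with_crosses(self, rng):
        xs = rng.standard_normal((6, 8))
        cs = dl.generate_crosses(8, 10, 3, xs, seed=0)
        p = dl.init_params("crosses_1h", seed=1, n_inputs=8, n_hidden=3, n_outputs=2, crosses=cs)
        st = p.new_field_state()
        x = rng.standard_normal(8)
        y = np.array([1.0, 0.0])
        assert finite_difference_check(p, x, y, 0.0, st, crosses=cs) < 1e-6

    def test_masked_gradient_entries_zero(self, rng):
        mask = block_receptive_field_mask(32, 16)
        p = dl.init_network([32, 2, 1], seed=6, masks=[mask, None])
        fp = dl.forward(p, rng.standard_normal(32), p.new_field_state(), 0.0)
        g = dl.gradients(p, rng.standard_normal(32), np.array([1.0]), fp)
        assert (g.dW[0][~mask] == 0.0).all()


class TestMomentumStep:
    def _setup(self, rng, mu, alpha):
        p = dl.init_network([6, 4, 2], seed=3)
        hp = dl.Hyperparams(eta=0.05, mu=mu, alpha=alpha)
        m = dl.MomentumState.for_params(p)
        x = rng.standard_normal(6)
        y = np.array([1.0, 0.0])
        fp = dl.forward(p, x, p.new_field_state(), 0.0)
        g = dl.gradients(p, x, y, fp)
        return p, hp, m, g

    def test_vanilla_gradient_descent(self, rng):
        p, hp, m, g = self._setup(rng, mu=0.0, alpha=0.0)
        before = [lw.W.copy() for lw in p.layers]
        dl.momentum_step(p, g, m, hp)
        for W0, lw, dW in zip(before, p.layers, g.dW):
            np.testing.assert_allclose(lw.W, W0 - hp.eta * dW, atol=1e-15)

    def test_first_velocity_is_minus_eta_grad(self, rng):
        p, hp, m, g = self._setup(rng, mu=0.9, alpha=0.0)
        dl.momentum_step(p, g, m, hp)
        assert m.initialized
        for V, dW in zip(m.V, g.dW):
            np.testing.assert_allclose(V, -hp.eta * dW, atol=1e-15)

    def test_decay_equals_full_cost_gradient_step(self, rng):
        """With mu=0 the (1-alpha) decay realizes exactly one gradient step
        on data + alpha/(2 eta) sum W^2: -eta * (alpha/eta) W = -alpha W."""
        for trial in range(100):
            trial_rng = np.random.default_rng(trial)
            p = dl.init_network([5, 3, 2], seed=trial)
            hp = dl.Hyperparams(eta=0.07, mu=0.0, alpha=0.013)
            x = trial_rng.standard_normal(5)
            y = np.array([1.0, 0.0])
            fp = dl.forward(p, x, p.new_field_state(), 0.0)
            g = dl.gradients(p, x, y, fp)
            expected = [
                lw.W - hp.eta * (dW + (hp.alpha / hp.eta) * lw.W)
                for lw, dW in zip(p.layers, g.dW)
            ]
            m = dl.MomentumState.for_params(p)
            dl.momentum_step(p, g, m, hp)
            for lw, want in zip(p.layers, expected):
                # identical up to one ulp at the weight scale:
                # (1-a)W vs W - aW associate differently
                np.testing.assert_allclose(lw.W, want, rtol=0, atol=1e-14)

    def test_biases_not_decayed(self, rng):
        p, hp, m, g = self._setup(rng, mu=0.0, alpha=0.5)
        b_before = [lw.b.copy() for lw in p.layers]
        dl.momentum_step(p, g, m, hp)
        for b0, lw, db in zip(b_before, p.layers, g.db):
            np.testing.assert_allclose(lw.b, b0 - hp.eta * db, atol=1e-15)

    def test_zero_gradient_geometric_velocity_decay(self, rng):
        p, hp, m, _ = self._setup(rng, mu=0.9, alpha=0.0)
        zero = Gradients(
            dW=[np.zeros_like(lw.W) for lw in p.layers],
            db=[np.zeros_like(lw.b) for lw in p.layers],
        )
        for V in m.V:
            V += 1.0
        v0 = [V.copy() for V in m.V]
        for k in range(1, 4):
            dl.momentum_step(p, zero, m, hp)
            for V, V0 in zip(m.V, v0):
                np.testing.assert_allclose(V, 0.9**k * V0, atol=1e-15)


class TestTrainLoop:
    def test_monotone_cost_on_separable_data(self):
        X, y = dl.gen_separable(120, 10, 3.0, seed=2)
        p = dl.init_network([10, 4, 1], seed=2)
        hp = dl.Hyperparams(eta=0.02, mu=0.0, epochs=20, seed=2)
        _, _, hist = dl.train(p, X, y.astype(float), hp)
        costs = [h.data_cost for h in hist]
        assert all(b <= a + 1e-9 for a, b in zip(costs, costs[1:]))

    def test_reaches_high_accuracy_on_separable(self):
        X, y = dl.gen_separable(200, 20, 2.0, seed=5)
        p = dl.init_network([20, 8, 1], seed=3)
        hp = dl.Hyperparams(eta=0.05, mu=0.9, epochs=50, seed=3)
        _, _, hist = dl.train(p, X, y.astype(float), hp)
        assert hist[-1].train_accuracy >= 0.99

    def test_masked_weights_stay_zero_through_training(self, tiny_normalized):
        train_set, _ = tiny_normalized
        p = dl.init_params("fftn_identifier", seed=0, n_inputs=64, block=16)
        y = (train_set.labels == 0).astype(float)
        hp = dl.Hyperparams(eta=0.02, mu=0.9, alpha=1e-4, amp1=0.1, epochs=10, seed=0)
        p, _, _ = dl.train(p, train_set.inputs, y, hp)
        assert (p.layers[0].W[~p.masks[0]] == 0.0).all()

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergence_aborts_with_diagnostic(self):
        X, y = dl.gen_separable(40, 5, 1.0, seed=0)
        p = dl.init_network([5, 3, 1], seed=0)
        p.layers[0].W *= np.inf  # poisoned weights -> non-finite cost
        hp = dl.Hyperparams(eta=0.1, epochs=1, seed=0)
        with pytest.raises(TrainingDiverged):
            dl.train(p, X, y.astype(float), hp)

    def test_minibatch_averages_gradients(self):
        """minibatch=n with mu=alpha=0 equals one step on the batch-mean
        gradient computed at the initial weights."""
        rng = np.random.default_rng(8)
        X = rng.standard_normal((4, 6))
        y = rng.integers(0, 2, size=4).astype(float)
        p0 = dl.init_network([6, 3, 1], seed=1)
        grads = []
        stref = p0.new_field_state()
        for x_i, y_i in zip(X, y):
            fp = dl.forward(p0.copy(), x_i, stref, 0.0, training=True)
            grads.append(dl.gradients(p0, x_i, np.array([y_i]), fp))
        mean_dW0 = np.mean([g.dW[0] for g in grads], axis=0)
        p = dl.init_network([6, 3, 1], seed=1)
        hp = dl.Hyperparams(eta=0.1, epochs=1, minibatch=4, seed=99)
        p, _, _ = dl.train(p, X, y, hp)
        p0_again = dl.init_network([6, 3, 1], seed=1)
        np.testing.assert_allclose(
            p.layers[0].W, p0_again.layers[0].W - 0.1 * mean_dW0, atol=1e-12
        )

    def test_seed_determinism_bit_identical(self, tiny_normalized):
        train_set, _ = tiny_normalized
        y = (train_set.labels == 1).astype(float)
        hists = []
        finals = []
        for _ in range(2):
            p = dl.init_params("fftn_identifier", seed=5, n_inputs=64, block=16)
            hp = dl.Hyperparams(eta=0.03, mu=0.8, alpha=1e-5, amp1=0.05, epochs=5, seed=5)
            p, st, hist = dl.train(p, train_set.inputs, y, hp)
            hists.append([(h.data_cost, h.train_accuracy) for h in hist])
            finals.append((p.layers[0].W.copy(), st.sum_z.copy()))
        assert hists[0] == hists[1]
        np.testing.assert_array_equal(finals[0][0], finals[1][0])
        np.testing.assert_array_equal(finals[0][1], finals[1][1])


class TestPowerLaw:
    def test_exact_recovery(self):
        n = np.array([15.0, 30.0, 60.0, 90.0])
        eps = 0.5 / n**0.3
        fit = dl.fit_power_law(np.column_stack([n, eps]))
        assert fit.c0 == pytest.approx(0.5, abs=1e-10)
        assert fit.rho == pytest.approx(0.3, abs=1e-10)
        assert fit.predict(50000.0) == pytest.approx(0.5 / 50000**0.3, rel=1e-10)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            dl.fit_power_law([(15.0, 0.2)])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            dl.fit_power_law([(15.0, 0.2), (30.0, -0.1)])

    def test_noisy_self_consistency(self):
        rng = np.random.default_rng(4)
        n_small = np.geomspace(10, 1000, 10)
        n_big = np.geomspace(10, 1000, 100)
        rho_true, c0_true = 0.4, 0.8
        def noisy(ns):
            return np.column_stack(
                [ns, c0_true / ns**rho_true * np.exp(rng.normal(0, 0.05, ns.size))]
            )
        fit_small = dl.fit_power_law(noisy(n_small))
        fit_big = dl.fit_power_law(noisy(n_big))
        assert abs(fit_small.rho - rho_true) < 0.1
        assert abs(fit_big.rho - fit_small.rho) < 0.1
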