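"""Fuzzy inference system, activations/losses, and the 1-D CNN."""

import numpy as np
import pytest

from pcgkit.fisxcnn import (MembershipFn, SugenoFIS, XCNNModel, activation,
                            fis_forward, fuzzy_risk_score, loss, membership,
                            softmax, xcnn_predict, xcnn_train)


class TestMembership:
    def test_gaussian_peaks_at_center(self):
        fn = MembershipFn("gaussian", (0.0, 1.0))
        assert membership(fn, 0.0) == pytest.approx(1.0)
        assert membership(fn, 1.0) == pytest.approx(np.exp(-0.5))

    def test_triangular_ramp_and_support(self):
        fn = MembershipFn("triangular", (0.0, 1.0, 2.0))
        assert membership(fn, 0.5) == pytest.approx(0.5)
        assert membership(fn, -0.1) == 0.0
        assert membership(fn, 2.1) == 0.0

    def test_bell_half_height_at_unit_width(self):
        fn = MembershipFn("bell", (1.0, 1.0, 0.0))
        assert membership(fn, 1.0) == pytest.approx(0.5)
        assert membership(fn, 0.0) == pytest.approx(1.0)

    def test_outputs_bounded(self):
        x = np.linspace(-5, 5, 101)
        for fn in (MembershipFn("gaussian", (0, 0.7)),
                   MembershipFn("triangular", (-1, 0, 2)),
                   MembershipFn("bell", (1.5, 2.0, 0.3))):
            vals = membership(fn, x)
            assert np.all((vals >= 0) & (vals <= 1))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MembershipFn("gaussian", (0.0, 0.0))
        with pytest.raises(ValueError):
            MembershipFn("triangular", (1.0, 0.5, 2.0))
        with pytest.raises(ValueError):
            MembershipFn("spline", (1.0,))


class TestFISForward:
    def test_single_rule_identity(self):
        fis = SugenoFIS(mfs_per_input=1, epochs=1)
        fis.fit(np.array([[0.2], [0.8]]), np.array([1.0, 1.0]))
        g, trace = fis_forward(fis, np.array([0.5]))
        w, e = fis.consequents_[0]
        assert g == pytest.approx(w * 0.5 + e)
        assert trace["normalized"].sum() == pytest.approx(1.0)

    def test_two_equal_rules_average(self):
        fis = SugenoFIS(mfs_per_input=2, epochs=1)
        fis.fit(np.linspace(0, 1, 9)[:, None], np.linspace(0, 1, 9))
        # at the midpoint both Gaussians fire equally
        fis.consequents_ = np.array([[0.0, 1.0], [0.0, 3.0]])
        g, _ = fis_forward(fis, np.array([0.5]))
        assert g == pytest.approx(2.0)

    def test_normalization_layer_sums_to_one(self):
        rng = np.random.default_rng(0)
        fis = SugenoFIS(mfs_per_input=2, epochs=2)
        X = rng.random((30, 2))
        fis.fit(X, rng.random(30))
        _, trace = fis.forward(X)
        np.testing.assert_allclose(trace["normalized"].sum(axis=1), 1.0,
                                   atol=1e-12)


class TestFISTraining:
    def test_exactly_representable_line(self):
        x = np.linspace(0, 1, 41)[:, None]
        y = 2 * x[:, 0] + 1
        fis = SugenoFIS(mfs_per_input=2, epochs=50, lr=0.05).fit(x, y)
        rmse = np.sqrt(np.mean((fis.predict(x) - y) ** 2))
        assert rmse < 1e-3

    def test_lse_step_never_increases_loss(self):
        rng = np.random.default_rng(2)
        X = rng.random((40, 2))
        y = np.sin(3 * X[:, 0]) + X[:, 1] ** 2
        fis = SugenoFIS(mfs_per_input=2, epochs=1).fit(X, y)
        for _ in range(5):
            before = float(np.mean((fis.predict(X) - y) ** 2))
            fis._solve_consequents(X, y)
            after = float(np.mean((fis.predict(X) - y) ** 2))
            assert after <= before + 1e-12
            dc, ds = fis.premise_gradients(X, y)
            fis.centers_ -= 0.01 * dc
            fis.sigmas_ -= 0.01 * ds

    def test_premise_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        X = rng.random((20, 2))
        y = np.sin(X[:, 0] * 3) + X[:, 1]
        fis = SugenoFIS(mfs_per_input=2, epochs=2, lr=0.01).fit(X, y)
        dc, ds = fis.premise_gradients(X, y)

        def current_loss():
            return float(np.mean((fis.forward(X)[0] - y) ** 2))

        eps = 1e-6
        for arr, grad in ((fis.centers_, dc), (fis.sigmas_, ds)):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                old = arr[ix]
                arr[ix] = old + eps
                lp = current_loss()
                arr[ix] = old - eps
                lm = current_loss()
                arr[ix] = old
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - grad[ix]) <= 1e-5 * max(1e-3, abs(fd))

    def test_rule_explosion_guard(self):
        X = np.random.default_rng(0).random((10, 7))
        with pytest.raises(ValueError):
            SugenoFIS().fit(X, np.zeros(10))

    def test_risk_score_clipped_and_separating(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.3, (30, 2)),
                       rng.normal(2, 0.3, (30, 2))])
        y = np.array([0.0] * 30 + [1.0] * 30)
        fis = SugenoFIS(mfs_per_input=2, epochs=30, lr=0.02).fit(X, y)
        scores = fuzzy_risk_score(fis, X)
        assert np.all((scores >= 0) & (scores <= 1))
        assert scores[:30].mean() < 0.5 < scores[30:].mean()


class TestActivationsLossesSoftmax:
    def test_activation_anchor_values(self):
        assert activation("sigmoid", 0.0) == pytest.approx(0.5)
        assert activation("relu", -3.0) == 0.0
        assert activation("leaky_relu", -2.0, {"m": 0.01}) == \
            pytest.approx(-0.02)
        assert activation("prelu", -2.0, {"u": 0.25}) == pytest.approx(-0.5)
        assert activation("tanh", 0.0) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            activation("swish", 0.0)

    def test_noisy_relu_seeded(self):
        a = activation("noisy_relu", np.zeros(5), {"seed": 3})
        b = activation("noisy_relu", np.zeros(5), {"seed": 3})
        np.testing.assert_array_equal(a, b)
        assert np.all(a >= 0)

    def test_loss_anchor_values(self):
        onehot = np.array([0.0, 1.0, 0.0])
        assert loss("cross_entropy", onehot, onehot) == pytest.approx(0.0)
        assert loss("euclidean", onehot, onehot) == 0.0
        assert loss("hinge", np.array([2.0]), np.array([1.0])) == 0.0
        assert loss("hinge", np.array([0.2]), np.array([1.0])) == \
            pytest.approx(0.8)

    def test_softmax_properties(self):
        p = softmax(np.zeros(5))
        np.testing.assert_allclose(p, 0.2)
        logits = np.array([1.0, -2.0, 0.5])
        np.testing.assert_allclose(softmax(logits), softmax(logits + 100.0))
        assert softmax(np.array([3.0, 1.0, -1.0])).sum() == \
            pytest.approx(1.0, abs=1e-12)


@pytest.fixture(scope="module")
def channel_fixture():
    """Five classes encoded by which channels carry periodic energy --
    the same structure the filter-bank segments exhibit."""
    rng = np.random.default_rng(3)
    patterns = [(1, 0, 0, 0), (0, 1, 0, 0), (0, 0, 1, 0), (0, 0, 0, 1),
                (1, 0, 0, 1)]
    X, y = [], []
    for c, pat in enumerate(patterns):
        for _ in range(20):
            sig = 0.3 * rng.standard_normal((4, 128))
            for ch, on in enumerate(pat):
                if on:
                    sig[ch] += np.abs(np.sin(np.linspace(0, 8 * np.pi, 128)))
            X.append(sig)
            y.append(f"C{c}")
    return np.array(X), np.array(y), rng.random(100)


class TestXCNN:
    def test_gradients_match_finite_differences(self):
        model = XCNNModel(c_in=2, n_classes=3, dropout=0.0, use_risk=True,
                          seed=0)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 2, 32))
        risk = rng.random(2)
        y = np.eye(3)[[0, 2]]
        model.loss_and_grads(x, y, risk, train=True)
        analytic = {k: layer.grads[name].copy()
                    for k, layer, name, _ in model.parameters()
                    if name in layer.grads}
        eps = 1e-6
        for key, layer, name, arr in model.parameters():
            g = analytic.get(key)
            if g is None:
                continue
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                old = arr[ix]
                arr[ix] = old + eps
                lp, _ = model.loss_and_grads(x, y, risk, train=True)
                arr[ix] = old - eps
                lm, _ = model.loss_and_grads(x, y, risk, train=True)
                arr[ix] = old
                fd = (lp - lm) / (2 * eps)
                assert np.isclose(g[ix], fd, rtol=1e-4, atol=1e-7), \
                    f"{key}{ix}: analytic {g[ix]} vs fd {fd}"

    def test_training_reaches_high_accuracy(self, channel_fixture):
        X, y, risk = channel_fixture
        model = xcnn_train(X, y, risk=risk, epochs=30, seed=3)
        assert model.train_accuracy_ >= 0.95
        assert model.loss_curve_[-1] < model.loss_curve_[0]

    def test_prediction_deterministic_and_normalized(self, channel_fixture):
        X, y, risk = channel_fixture
        model = xcnn_train(X[:40], y[:40], risk=risk[:40], epochs=5, seed=0)
        p1, l1 = xcnn_predict(model, X[:10], risk[:10])
        p2, l2 = xcnn_predict(model, X[:10], risk[:10])
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-12)

    def test_risk_fusion_changes_only_dense_width(self):
        with_risk = XCNNModel(c_in=1, n_classes=5, use_risk=True, seed=0)
        without = XCNNModel(c_in=1, n_classes=5, use_risk=False, seed=0)
        assert with_risk.dense.params["W"].shape[0] == 65
        assert without.dense.params["W"].shape[0] == 64
        assert with_risk.conv_stack[0].params["W"].shape == \
            without.conv_stack[0].params["W"].shape

    def test_nan_input_aborts_with_diagnostic(self, channel_fixture):
        X, y, risk = channel_fixture
        bad = X[:20].copy()
        bad[0, 0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            xcnn_train(bad, y[:20], risk=risk[:20], epochs=2, seed=0)
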