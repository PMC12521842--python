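"""LV-PSO: information gain, LVQ fitness, swarm rules, selection."""

import numpy as np
import pytest

from pcgkit.lvpso import (LVPSOSelector, Swarm, classify_accel, info_gain,
                          init_swarm, lvq_fitness, lvq_predict, lvq_train,
                          pso_step, select_features, select_inertia)


class TestInfoGain:
    def test_perfect_binary_predictor_gains_one_bit(self):
        y = np.array([0, 1] * 50)
        X = y[:, None].astype(float)
        gains = info_gain(X, y, n_bins=2)
        assert gains[0] == pytest.approx(1.0, abs=1e-9)

    def test_independent_feature_gains_near_zero(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 4000)
        X = rng.standard_normal((4000, 1))
        assert info_gain(X, y)[0] < 0.05

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 3, 300)
        X = rng.standard_normal((300, 2)) + y[:, None]
        np.testing.assert_allclose(info_gain(X, y),
                                   info_gain(X * 137.0 - 5.0, y))

    def test_constant_label_rejected(self):
        with pytest.raises(ValueError):
            info_gain(np.random.default_rng(0).random((10, 2)), np.zeros(10))


class TestLVQ:
    def test_full_rate_update_jumps_to_sample(self):
        X = np.array([[2.0, 2.0]])
        y = np.array(["a"])
        # single class, alpha=1, one epoch: the prototype (class mean = the
        # sample itself already) stays at the sample
        book = lvq_train(X, y, gains=np.ones(2), alpha=1.0, epochs=1, seed=0)
        np.testing.assert_allclose(book.z[0], X[0])

    def test_pull_update_rule(self):
        # two classes; correct winner moves exactly by a*(x - z)
        X = np.array([[0.0], [4.0]])
        y = np.array(["a", "b"])
        book = lvq_train(X, y, gains=np.ones(1), alpha=0.5, epochs=1, seed=0)
        assert lvq_predict(book, np.array([[0.1]]))[0] == "a"

    def test_separated_gaussians_low_error(self):
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = np.vstack([rng.normal(0, 0.5, (40, 3)),
                           rng.normal(3, 0.5, (40, 3))])
            y = np.array(["a"] * 40 + ["b"] * 40)
            errs.append(lvq_fitness(X, y, np.ones(3), seed=seed))
        assert np.mean(errs) < 0.1

    def test_zero_mask_is_uninformative(self, small_label_set):
        X, y = small_label_set
        err = lvq_fitness(X, y, np.zeros(X.shape[1]), seed=0)
        # with all features masked out the held-out error is at chance
        # level for two balanced classes (all distances tie at zero)
        assert err >= 0.3


class TestSwarmRules:
    @pytest.mark.parametrize("e,cls", [(0.5, "L"), (1.0, "M"), (1.6, "H"),
                                       (0.0, "L"), (2.0, "H"), (0.84, "L"),
                                       (0.85, "M"), (1.24, "M"), (1.25, "H")])
    def test_acceleration_classing(self, e, cls):
        assert classify_accel(e) == cls

    def test_acceleration_outside_range_rejected(self):
        with pytest.raises(ValueError):
            classify_accel(2.1)

    @pytest.mark.parametrize("c1,c2,w", [("L", "L", 0.9), ("H", "H", 0.4),
                                         ("L", "H", 0.65), ("M", "M", 0.65),
                                         ("M", "H", 0.65), ("L", "M", 0.65)])
    def test_inertia_selection(self, c1, c2, w):
        assert select_inertia(c1, c2) == pytest.approx(w)

    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError):
            select_inertia("L", "X")


class TestPSO:
    @staticmethod
    def sphere(x):
        return float(np.sum((x - 0.5) ** 2))

    def test_gbest_history_non_increasing(self):
        rng = np.random.default_rng(7)
        swarm = init_swarm(10, 3, self.sphere, rng)
        for _ in range(50):
            pso_step(swarm, self.sphere, rng)
        h = np.array(swarm.history)
        assert np.all(np.diff(h) <= 0)

    def test_positions_stay_clamped(self):
        rng = np.random.default_rng(8)
        swarm = init_swarm(8, 4, self.sphere, rng)
        for _ in range(30):
            pso_step(swarm, self.sphere, rng)
            for p in swarm.particles:
                assert np.all((p.x >= 0) & (p.x <= 1))

    def test_sphere_convergence(self):
        rng = np.random.default_rng(7)
        swarm = init_swarm(30, 2, self.sphere, rng)
        for _ in range(200):
            pso_step(swarm, self.sphere, rng)
        assert swarm.gbest_fit < 1e-3

    def test_empty_swarm_rejected(self):
        with pytest.raises(ValueError):
            pso_step(Swarm(particles=[], gbest=np.zeros(1), gbest_fit=0.0),
                     self.sphere, np.random.default_rng(0))


def _planted_dataset(seed, n=120, d_informative=5, d_noise=15):
    """Five individually weak, jointly necessary informative features:
    each carries an independent 0.9-sd class shift, so dropping any one
    measurably raises the LVQ error."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.standard_normal((n, d_informative + d_noise))
    X[:, :d_informative] += 0.9 * y[:, None]
    return X, y.astype(str)


class TestSelection:
    def test_planted_feature_recovery(self):
        recalls = []
        for seed in range(10):
            X, y = _planted_dataset(seed)
            sel = LVPSOSelector(n_particles=15, n_iter=25, seed=seed).fit(X, y)
            recalls.append(sel.mask_[:5].mean())
        assert np.mean(recalls) >= 0.8

    def test_selected_subset_no_worse_than_all_features(self):
        X, y = _planted_dataset(3)
        sel = LVPSOSelector(n_particles=12, n_iter=15, seed=3).fit(X, y)
        mu, sd = X.mean(0), X.std(0)
        Xs = (X - mu) / sd
        gains = info_gain(Xs, y)
        err_sel = lvq_fitness(Xs * sel.mask_, y, np.ones(X.shape[1]),
                              gains=gains, seed=3)
        err_all = lvq_fitness(Xs, y, np.ones(X.shape[1]), gains=gains, seed=3)
        assert err_sel <= err_all + 0.05

    def test_single_feature_shortcut(self):
        X = np.random.default_rng(0).random((20, 1))
        y = np.array(["a", "b"] * 10)
        sel = LVPSOSelector().fit(X, y)
        np.testing.assert_array_equal(sel.mask_, [True])

    def test_seeded_determinism(self):
        X, y = _planted_dataset(5)
        a = LVPSOSelector(n_particles=8, n_iter=8, seed=2).fit(X, y)
        b = LVPSOSelector(n_particles=8, n_iter=8, seed=2).fit(X, y)
        np.testing.assert_array_equal(a.mask_, b.mask_)
        np.testing.assert_array_equal(a.weights_, b.weights_)

    def test_functional_wrapper_report(self):
        X, y = _planted_dataset(1)
        mask, report = select_features(X, y, n_particles=8, n_iter=5, seed=1)
        assert mask.any()
        assert len(report.history) == 6
        assert report.seed == 1
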