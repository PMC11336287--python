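"""SMA operators, ISMA and CRFSMA behavioral contracts."""

import numpy as np
import pytest

from sludgeopt.nds import dominance_matrix
from sludgeopt.optimizers import (
    LevyConfig,
    SmaConfig,
    chaos_perturb,
    crfsma_optimize,
    isma_minimize,
    levy_step,
    logistic_chaos_sequence,
    mantegna_sigma,
    obl_opposite,
    sma_move,
    sma_weights,
)


class TestSmaWeights:
    def test_best_individual_weight_is_one(self, rng):
        C = np.array([1.0, 3.0, 5.0])
        W = sma_weights(C, rng, dim=4)
        np.testing.assert_allclose(W[0], 1.0)  # log10(1) = 0 for the best

    def test_worst_individual_bounds(self):
        # argument of the log is 2 at the worst fitness: W = 1 +/- r*log10(2)
        rng = np.random.default_rng(0)
        C = np.array([1.0, 2.0, 3.0, 10.0])
        for _ in range(50):
            W = sma_weights(C, rng, dim=3)
            assert np.all(W >= 1.0 - np.log10(2.0) - 1e-12)
            assert np.all(W <= 1.0 + np.log10(2.0) + 1e-12)

    def test_elite_half_above_one_mean_half_below(self, rng):
        C = np.array([1.0, 2.0, 3.0, 4.0])
        W = sma_weights(C, rng, dim=1)
        assert np.all(W[:2] >= 1.0) and np.all(W[2:] <= 1.0)

    def test_degenerate_equal_fitness(self, rng):
        W = sma_weights(np.full(6, 2.5), rng, dim=3)
        np.testing.assert_allclose(W, 1.0)

    def test_empty_population_rejected(self, rng):
        with pytest.raises(ValueError):
            sma_weights(np.array([]), rng)


class TestSmaMove:
    def test_final_iteration_approach_collapses_to_best(self):
        """At t = t_max the step range a is 0, so the food-approach branch
        returns exactly the guiding position."""
        rng = np.random.default_rng(1)
        cfg = SmaConfig(n_pop=6, max_iter=50, z=0.0, lower=-5.0, upper=5.0)
        Y = rng.uniform(-5, 5, size=(6, 3))
        C = np.arange(6.0) + 10.0
        yb = np.array([1.0, -2.0, 3.0])
        W = sma_weights(C, rng, dim=3)
        out = sma_move(Y, C, yb, W, t=50, cfg=cfg, rng=rng, DO=0.0)
        # p = tanh|C - 0| ~ 1 for all: every row takes the approach branch
        np.testing.assert_allclose(out, np.tile(yb, (6, 1)))

    def test_best_individual_contracts(self):
        """An individual at the global best (p = tanh 0 = 0) always takes
        the multiplicative contraction branch."""
        rng = np.random.default_rng(2)
        cfg = SmaConfig(n_pop=4, max_iter=10, z=0.0, lower=-8.0, upper=8.0)
        Y = np.full((4, 2), 4.0)
        C = np.array([7.0, 9.0, 9.0, 9.0])
        W = np.ones((4, 2))
        for t in (2, 5, 8):
            b = 1.0 - t / 10.0
            for _ in range(20):
                out = sma_move(Y, C, Y[0], W, t=t, cfg=cfg, rng=rng, DO=7.0)
                assert np.all(np.abs(out[0]) <= np.abs(Y[0]) * b + 1e-12)

    def test_positions_clamped_to_bounds(self, rng):
        cfg = SmaConfig(n_pop=30, max_iter=100, lower=0.0, upper=1.0)
        Y = rng.random((30, 5))
        C = rng.random(30)
        W = sma_weights(C, rng, dim=5)
        out = sma_move(Y, C, Y[0], W, t=1, cfg=cfg, rng=rng)
        assert np.all(out >= 0.0) and np.all(out <= 1.0)

    def test_iteration_beyond_budget_rejected(self, rng):
        cfg = SmaConfig(n_pop=4, max_iter=10)
        with pytest.raises(ValueError):
            sma_move(np.zeros((4, 2)), np.zeros(4), np.zeros(2), np.ones((4, 2)), t=11, cfg=cfg, rng=rng)


class TestOppositionBasedLearning:
    def test_midpoint_fixed_point(self):
        y = np.array([0.5, 0.0])
        ub, lb = np.array([1.0, 2.0]), np.array([0.0, -2.0])
        np.testing.assert_allclose(obl_opposite(y, ub, lb), y)

    def test_hand_value(self):
        assert obl_opposite(np.array([0.3]), 1.0, 0.0)[0] == pytest.approx(0.7)

    def test_involution(self, rng):
        ub, lb = rng.random(6) + 1.0, -rng.random(6)
        y = lb + (ub - lb) * rng.random(6)
        np.testing.assert_allclose(obl_opposite(obl_opposite(y, ub, lb), ub, lb), y)


class TestLevyFlight:
    def test_sigma_closed_form_at_default_beta(self):
        # Mantegna constant at beta = 1.5, checked against an independent
        # evaluation of the Gamma-function expression
        from math import gamma, pi, sin

        beta = 1.5
        expected = (
            gamma(1 + beta) * sin(pi * beta / 2)
            / (gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))
        ) ** (1 / beta)
        assert mantegna_sigma(1.5) == pytest.approx(expected, rel=1e-14)
        assert mantegna_sigma(1.5) == pytest.approx(0.6966, abs=2e-4)

    def test_additive_zero_scale_is_identity(self, rng):
        yb = np.array([0.2, 0.8])
        out = levy_step(yb, 2, LevyConfig(s=0.0, additive=True), rng, 0.0, 1.0)
        np.testing.assert_allclose(out, yb)

    def test_steps_heavy_tailed(self):
        rng = np.random.default_rng(7)
        cfg = LevyConfig()
        sigma = mantegna_sigma(cfg.beta)
        u = rng.standard_normal(100_000)
        v = rng.standard_normal(100_000)
        steps = cfg.s * sigma * u / np.abs(v) ** (1.0 / cfg.beta)
        clipped = np.clip(steps, -1e3, 1e3)  # finite-sample kurtosis guard
        kurt = np.mean((clipped - clipped.mean()) ** 4) / np.var(clipped) ** 2
        assert kurt > 10.0  # far beyond the Gaussian value of 3

    def test_respects_bounds(self, rng):
        out = levy_step(np.full(4, 0.5), 4, LevyConfig(), rng, 0.0, 1.0)
        assert np.all(out >= 0.0) and np.all(out <= 1.0)


class TestLogisticChaos:
    def test_hand_iteration(self):
        seq = logistic_chaos_sequence(0.2, 3)
        assert seq[1] == pytest.approx(0.64)
        assert seq[2] == pytest.approx(4 * 0.64 * 0.36)

    @pytest.mark.parametrize("bad", [0.0, 0.25, 0.5, 0.75, 1.0, -0.1, 1.1])
    def test_forbidden_seeds_rejected(self, bad):
        with pytest.raises(ValueError):
            logistic_chaos_sequence(bad, 5)

    def test_075_would_be_fixed_point(self):
        assert 4 * 0.75 * (1 - 0.75) == pytest.approx(0.75)

    def test_ergodic_occupancy(self):
        seq = logistic_chaos_sequence(0.7, 100_000)
        hist, _ = np.histogram(seq, bins=100, range=(0.0, 1.0))
        assert np.all(hist > 0)
        assert np.all((seq >= 0.0) & (seq <= 1.0))


class TestChaosPerturb:
    def test_endpoints_and_hand_value(self):
        lb, ub = np.zeros(3), np.array([10.0, 10.0, 10.0])
        y = np.array([1.0, 2.0, 3.0])
        assert chaos_perturb(y, 1, 0.0, lb, ub)[1] == 0.0
        assert chaos_perturb(y, 2, 0.64, lb, ub)[2] == pytest.approx(6.4)

    def test_other_coordinates_bit_identical(self):
        lb, ub = np.zeros(3), np.ones(3)
        y = np.array([0.111, 0.222, 0.333])
        out = chaos_perturb(y, 0, 0.9, lb, ub)
        assert out[1] == y[1] and out[2] == y[2]

    def test_invalid_chaotic_value(self):
        with pytest.raises(ValueError):
            chaos_perturb(np.zeros(2), 0, 1.5, np.zeros(2), np.ones(2))


class TestIsma:
    def test_sphere_convergence(self):
        cfg = SmaConfig(n_pop=30, max_iter=200, lower=-10.0, upper=10.0, seed=3)
        res = isma_minimize(lambda X: (np.atleast_2d(X) ** 2).sum(axis=1), 10, cfg)
        assert res["best_f"] < 1e-3

    def test_best_so_far_monotone(self):
        cfg = SmaConfig(n_pop=12, max_iter=60, lower=-5.0, upper=5.0, seed=9)
        res = isma_minimize(lambda X: (np.atleast_2d(X) ** 2).sum(axis=1), 4, cfg)
        assert np.all(np.diff(res["history"]) <= 0.0)

    def test_seed_reproducibility(self):
        def f(X):
            X = np.atleast_2d(X)
            return ((X - 0.3) ** 2).sum(axis=1)

        cfg = SmaConfig(n_pop=10, max_iter=40, lower=0.0, upper=1.0, seed=5)
        a = isma_minimize(f, 3, cfg)
        b = isma_minimize(f, 3, cfg)
        assert a["history"].tolist() == b["history"].tolist()
        np.testing.assert_array_equal(a["best_x"], b["best_x"])

    def test_nan_objective_treated_as_worst(self):
        def f(X):
            X = np.atleast_2d(X)
            v = (X**2).sum(axis=1)
            v[X[:, 0] > 0.5] = np.nan
            return v

        cfg = SmaConfig(n_pop=8, max_iter=30, lower=0.0, upper=1.0, seed=1)
        res = isma_minimize(f, 2, cfg)
        assert np.isfinite(res["best_f"])


class TestCrfsma:
    @staticmethod
    def _bi_objective(X):
        X = np.atleast_2d(X)
        f1 = X[:, 0]
        g = 1.0 + X[:, 1:].mean(axis=1)
        return np.column_stack([f1, g * (1.0 - np.sqrt(f1 / g))])

    def test_duplicate_objectives_collapse(self):
        def twin(X):
            X = np.atleast_2d(X)
            s = (X**2).sum(axis=1)
            return np.column_stack([s, s])

        cfg = SmaConfig(n_pop=20, max_iter=60, lower=-2.0, upper=2.0, seed=4)
        arch = crfsma_optimize(twin, 5, 2, cfg)
        assert arch.F[:, 0].min() < 0.05  # collapses to the single optimum

    def test_front_internally_nondominated(self):
        cfg = SmaConfig(n_pop=24, max_iter=80, lower=0.0, upper=1.0, seed=6)
        arch = crfsma_optimize(self._bi_objective, 6, 2, cfg)
        dom = dominance_matrix(arch.F)
        assert not dom.any()

    def test_seed_reproducibility(self):
        cfg = SmaConfig(n_pop=16, max_iter=30, lower=0.0, upper=1.0, seed=11)
        a = crfsma_optimize(self._bi_objective, 5, 2, cfg)
        b = crfsma_optimize(self._bi_objective, 5, 2, cfg)
        np.testing.assert_array_equal(a.F, b.F)
        np.testing.assert_array_equal(a.X, b.X)

    def test_chaos_redraw_mode_runs(self):
        cfg = SmaConfig(n_pop=12, max_iter=20, lower=0.0, upper=1.0, seed=2)
        arch = crfsma_optimize(self._bi_objective, 5, 2, cfg, chaos_mode="redraw")
        assert len(arch.F) >= 1

    def test_archive_export(self, tmp_path):
        cfg = SmaConfig(n_pop=12, max_iter=15, lower=0.0, upper=1.0, seed=8)
        arch = crfsma_optimize(self._bi_objective, 4, 2, cfg)
        arch.to_csv(tmp_path / "front.csv")
        arch.to_json(tmp_path / "run.json")
        import json

        rec = json.loads((tmp_path / "run.json").read_text())
        assert rec["config"]["seed"] == 8
        assert len(rec["front_F"]) == len(arch.F)
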