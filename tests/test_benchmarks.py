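"""Analytic test problems, true fronts and the IGD harness."""

import numpy as np
import pytest

from sludgeopt.benchmarks import (
    PROBLEM_NAMES,
    evaluate_problem,
    get_problem,
    igd,
    run_benchmark,
    true_front_sample,
)
from sludgeopt.nds import dominance_matrix


def reference_eval(name, x):
    """Independent plain-Python implementation of the published formulas."""
    import math

    x = list(map(float, x))
    n = len(x)
    if name == "ZDT1":
        g = 1 + 9 * sum(x[1:]) / (n - 1)
        return [x[0], g * (1 - math.sqrt(x[0] / g))]
    if name == "ZDT2":
        g = 1 + 9 * sum(x[1:]) / (n - 1)
        return [x[0], g * (1 - (x[0] / g) ** 2)]
    if name == "ZDT3":
        g = 1 + 9 * sum(x[1:]) / (n - 1)
        return [x[0], g * (1 - math.sqrt(x[0] / g) - x[0] / g * math.sin(10 * math.pi * x[0]))]
    if name == "UF1":
        j1 = [j for j in range(2, n + 1) if j % 2 == 1]
        j2 = [j for j in range(2, n + 1) if j % 2 == 0]
        y = {j: x[j - 1] - math.sin(6 * math.pi * x[0] + j * math.pi / n) for j in range(2, n + 1)}
        return [
            x[0] + 2 / len(j1) * sum(y[j] ** 2 for j in j1),
            1 - math.sqrt(x[0]) + 2 / len(j2) * sum(y[j] ** 2 for j in j2),
        ]
    if name == "UF2":
        j1 = [j for j in range(2, n + 1) if j % 2 == 1]
        j2 = [j for j in range(2, n + 1) if j % 2 == 0]

        def yj(j):
            a = 0.3 * x[0] ** 2 * math.cos(24 * math.pi * x[0] + 4 * j * math.pi / n) + 0.6 * x[0]
            if j % 2 == 1:
                return x[j - 1] - a * math.cos(6 * math.pi * x[0] + j * math.pi / n)
            return x[j - 1] - a * math.sin(6 * math.pi * x[0] + j * math.pi / n)

        return [
            x[0] + 2 / len(j1) * sum(yj(j) ** 2 for j in j1),
            1 - math.sqrt(x[0]) + 2 / len(j2) * sum(yj(j) ** 2 for j in j2),
        ]
    if name == "UF3":
        j1 = [j for j in range(2, n + 1) if j % 2 == 1]
        j2 = [j for j in range(2, n + 1) if j % 2 == 0]
        y = {
            j: x[j - 1] - x[0] ** (0.5 * (1.0 + 3.0 * (j - 2) / (n - 2)))
            for j in range(2, n + 1)
        }

        def mix(js):
            s = sum(y[j] ** 2 for j in js)
            p = 1.0
            for j in js:
                p *= math.cos(20 * y[j] * math.pi / math.sqrt(j))
            return (4 * s - 2 * p + 2) / len(js)

        return [x[0] + 2 * mix(j1), 1 - math.sqrt(x[0]) + 2 * mix(j2)]
    if name in ("DTLZ1", "DTLZ2", "DTLZ3", "DTLZ7"):
        xm = x[2:]
        if name in ("DTLZ1", "DTLZ3"):
            g = 100 * (len(xm) + sum((xi - 0.5) ** 2 - math.cos(20 * math.pi * (xi - 0.5)) for xi in xm))
        elif name == "DTLZ2":
            g = sum((xi - 0.5) ** 2 for xi in xm)
        else:
            g = 1 + 9 * sum(xm) / len(xm)
        if name == "DTLZ1":
            return [
                0.5 * x[0] * x[1] * (1 + g),
                0.5 * x[0] * (1 - x[1]) * (1 + g),
                0.5 * (1 - x[0]) * (1 + g),
            ]
        if name in ("DTLZ2", "DTLZ3"):
            return [
                (1 + g) * math.cos(x[0] * math.pi / 2) * math.cos(x[1] * math.pi / 2),
                (1 + g) * math.cos(x[0] * math.pi / 2) * math.sin(x[1] * math.pi / 2),
                (1 + g) * math.sin(x[0] * math.pi / 2),
            ]
        h = 3 - sum(fi / (1 + g) * (1 + math.sin(3 * math.pi * fi)) for fi in x[:2])
        return [x[0], x[1], (1 + g) * h]
    raise ValueError(name)


class TestProblemFormulas:
    def test_zdt1_anchor_points(self):
        x = np.zeros(30)
        np.testing.assert_allclose(evaluate_problem("ZDT1", x), [0.0, 1.0])
        x[0] = 1.0
        np.testing.assert_allclose(evaluate_problem("ZDT1", x), [1.0, 0.0], atol=1e-14)

    def test_dtlz2_on_sphere_when_distance_vars_centered(self):
        x = np.full(10, 0.5)
        x[0], x[1] = 0.3, 0.8
        f = evaluate_problem("DTLZ2", x)
        assert (f**2).sum() == pytest.approx(1.0)

    def test_wrong_dimension_rejected(self):
        with pytest.raises(ValueError):
            get_problem("ZDT1")(np.zeros((3, 12)))

    @pytest.mark.parametrize("name", PROBLEM_NAMES)
    def test_vectorized_matches_independent_reference(self, name):
        prob = get_problem(name)
        rng = np.random.default_rng(hash(name) % 2**31)
        X = prob.lower + (prob.upper - prob.lower) * rng.random((100, prob.dim))
        F = prob(X)
        for k in range(100):
            np.testing.assert_allclose(
                F[k], reference_eval(name, X[k]), rtol=1e-10, atol=1e-10
            )

    def test_table_configurations(self):
        for name in PROBLEM_NAMES:
            p = get_problem(name)
            if name.startswith(("UF", "ZDT")):
                assert (p.dim, p.n_obj) == (30, 2)
            else:
                assert (p.dim, p.n_obj) == (10, 3)
            assert p.max_iter == 1000

    def test_printed_bounds_variant_exposed(self):
        p = get_problem("ZDT2", printed_bounds=True)
        assert p.lower[1] == -5.0 and p.upper[1] == 5.0
        assert get_problem("ZDT2").lower[1] == 0.0


class TestTrueFronts:
    def test_zdt1_three_points(self):
        P = true_front_sample("ZDT1", 3)
        np.testing.assert_allclose(P, [[0, 1], [0.5, 1 - np.sqrt(0.5)], [1, 0]])

    @pytest.mark.parametrize("name", PROBLEM_NAMES)
    def test_front_samples_nondominated(self, name):
        P = true_front_sample(name, 200)
        assert not dominance_matrix(P).any()

    def test_dtlz1_simplex_sum(self):
        P = true_front_sample("DTLZ1", 300)
        np.testing.assert_allclose(P.sum(axis=1), 0.5, atol=1e-12)

    def test_dtlz2_unit_sphere(self):
        P = true_front_sample("DTLZ2", 300)
        np.testing.assert_allclose(np.linalg.norm(P, axis=1), 1.0, atol=1e-12)

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            true_front_sample("ZDT1", 1)


class TestIgd:
    def test_superset_gives_zero(self, rng):
        P = rng.random((20, 2))
        Q = np.vstack([P, rng.random((10, 2))])
        assert igd(P, Q) == 0.0

    def test_hand_value(self):
        P = np.array([[0.0, 1.0], [1.0, 0.0]])
        Q = np.array([[0.0, 0.0]])
        assert igd(P, Q) == pytest.approx(1.0)

    def test_nonincreasing_when_solutions_added(self, rng):
        P = rng.random((50, 3))
        Q = rng.random((10, 3))
        more = np.vstack([Q, rng.random((10, 3))])
        assert igd(P, more) <= igd(P, Q)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            igd(np.empty((0, 2)), np.ones((2, 2)))


class TestHarness:
    def test_single_run_statistics(self):
        prob = get_problem("ZDT1")
        res = run_benchmark(prob, n_runs=1, base_seed=0, max_iter=5, n_pop=12, ref_size=100)
        assert res.avg == res.min == res.max
        assert res.std == 0.0

    def test_true_front_optimizer_scores_near_zero(self):
        prob = get_problem("ZDT1")

        def oracle_optimizer(problem, cfg):
            return true_front_sample(problem.name, 500)

        res = run_benchmark(prob, n_runs=2, base_seed=1, optimizer=oracle_optimizer, ref_size=1000)
        assert res.avg < 1e-3  # only sampling resolution remains

    def test_table_layout(self):
        from sludgeopt.benchmarks import benchmark_table

        prob = get_problem("ZDT1")
        res = run_benchmark(prob, n_runs=2, base_seed=0, max_iter=5, n_pop=12, ref_size=100)
        df = benchmark_table([res])
        assert list(df.columns[:5]) == ["problem", "Avg", "StD", "Min", "Max"]
        assert df.loc[0, "runs"] == 2
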