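"""OAT scans, Saltelli sampling and the native Sobol estimators."""

import numpy as np
import pytest
from scipy.stats import kstest

from mitofission import (
    CASES,
    DimensionalParams,
    GSACase,
    evaluate_outputs,
    integrate_cumulative_tf,
    oat_scan,
    saltelli_sample,
    simulate,
    sobol_indices,
)


class TestSaltelliSample:
    @pytest.mark.parametrize(
        "case_id,rows", [("case1", 20480), ("case2", 24576)]
    )
    def test_row_counts(self, case_id, rows):
        """base_N=2048 gives N*(2D+2) evaluation points per case."""
        s = saltelli_sample(CASES[case_id], 2048, seed=0)
        assert s.n_rows == rows
        assert s.rows.shape == (rows, CASES[case_id].dim)

    @pytest.mark.parametrize("bad", [0, 3, 100, 2047])
    def test_base_must_be_power_of_two(self, bad):
        with pytest.raises(ValueError):
            saltelli_sample(CASES["case1"], bad, seed=0)

    def test_bounds_and_uniform_marginals(self):
        case = CASES["case2"]
        s = saltelli_sample(case, 2048, seed=11)
        rows = s.rows
        for j, (lo, hi) in enumerate(case.bounds):
            col = rows[:, j]
            assert col.min() >= lo and col.max() <= hi
            # KS against the target uniform on the A block alone (i.i.d.-ish)
            stat = kstest(s.A[:, j], "uniform", args=(lo, hi - lo)).statistic
            assert stat < 0.05

    def test_hybrid_block_structure(self):
        s = saltelli_sample(CASES["case1"], 64, seed=2)
        for i in range(4):
            np.testing.assert_array_equal(s.AB[i][:, i], s.B[:, i])
            mask = np.arange(4) != i
            np.testing.assert_array_equal(s.AB[i][:, mask], s.A[:, mask])

    def test_deterministic_given_seed(self):
        a = saltelli_sample(CASES["case1"], 128, seed=5).rows
        b = saltelli_sample(CASES["case1"], 128, seed=5).rows
        np.testing.assert_array_equal(a, b)


def _unit_case(d, name="unit"):
    return GSACase(name, tuple(f"x{i}" for i in range(1, d + 1)),
                   tuple((0.0, 1.0) for _ in range(d)), "dimensional")


class TestSobolEstimators:
    def test_additive_function_closed_form(self):
        """Y = sum a_i X_i: S1_i = a_i^2/sum a_j^2, ST = S1, S2 = 0."""
        coef = np.array([1.0, 2.0, 3.0, 0.5])
        case = _unit_case(4)
        s = saltelli_sample(case, 1024, seed=7)
        y = evaluate_outputs(case, s, model=lambda r: float(coef @ r))
        res = sobol_indices(y, s, n_boot=300, seed=1)
        exact = coef ** 2 / np.sum(coef ** 2)
        np.testing.assert_allclose(res.S1, exact, atol=0.02)
        np.testing.assert_allclose(res.ST, exact, atol=0.02)
        for (lo, hi), s1 in zip(res.S1_ci, exact):
            assert lo - 0.02 <= s1 <= hi + 0.02
        for pair, v in res.S2.items():
            lo, hi = res.S2_ci[pair]
            assert lo <= 0.0 <= hi  # true interaction is exactly zero
            assert abs(v) < 0.02

    def test_ishigami_benchmark(self):
        """Nonadditive benchmark with known variance decomposition."""
        A, B = 7.0, 0.1
        case = GSACase("ishigami", ("x1", "x2", "x3"),
                       tuple((-np.pi, np.pi) for _ in range(3)),
                       "dimensional")
        s = saltelli_sample(case, 1024, seed=3)
        y = evaluate_outputs(
            case, s,
            model=lambda r: np.sin(r[0]) + A * np.sin(r[1]) ** 2
            + B * r[2] ** 4 * np.sin(r[0]),
        )
        res = sobol_indices(y, s, n_boot=300, seed=2)
        V = A**2 / 8 + B * np.pi**4 / 5 + B**2 * np.pi**8 / 18 + 0.5
        s1_exact = np.array(
            [0.5 * (1 + B * np.pi**4 / 5) ** 2 / V, A**2 / 8 / V, 0.0])
        s13 = 8 * B**2 * np.pi**8 / 225 / V
        st_exact = s1_exact + np.array([s13, 0.0, s13])
        np.testing.assert_allclose(res.S1, s1_exact, atol=0.03)
        np.testing.assert_allclose(res.ST, st_exact, atol=0.03)
        assert res.S2[("x1", "x3")] == pytest.approx(s13, abs=0.05)
        assert res.significant(2)[("x1", "x3")]

    def test_constant_output_rejected(self):
        case = _unit_case(3)
        s = saltelli_sample(case, 64, seed=0)
        with pytest.raises(ValueError, match="constant"):
            sobol_indices(np.ones(s.n_rows), s, n_boot=10)

    def test_layout_length_checked(self):
        case = _unit_case(3)
        s = saltelli_sample(case, 64, seed=0)
        with pytest.raises(ValueError, match="layout"):
            sobol_indices(np.ones(17), s)

    def test_bootstrap_reproducible(self):
        case = _unit_case(3)
        s = saltelli_sample(case, 256, seed=9)
        y = evaluate_outputs(case, s, model=lambda r: r[0] + 0.5 * r[1] ** 2)
        a = sobol_indices(y, s, n_boot=100, seed=4)
        b = sobol_indices(y, s, n_boot=100, seed=4)
        np.testing.assert_array_equal(a.S1_ci, b.S1_ci)


class TestModelOutputs:
    def test_pipeline_deterministic(self, table1):
        v1 = integrate_cumulative_tf(table1, rtol=1e-6, atol=1e-9)
        v2 = integrate_cumulative_tf(table1, rtol=1e-6, atol=1e-9)
        assert v1 == v2

    def test_vanishing_k_plus_gives_no_fission(self):
        """Without elongation no oligomer reaches the fission threshold."""
        p = DimensionalParams(k_plus=1e-6)
        assert integrate_cumulative_tf(p, rtol=1e-6, atol=1e-9) < 1e-6

    def test_case_params_fix_unvaried_at_canonical(self):
        p = CASES["case1"].make_params(np.array([2.0, 0.1, 3.0, 0.5]))
        assert (p.a, p.gamma, p.T_total, p.M_total) == (5.0, 0.1, 20.0, 15.0)
        p2 = CASES["case2"].make_params(np.array([2.0, 0.1, 3.0, 0.5, 10.0]))
        assert p2.M_total == 10.0 and p2.T_total == 20.0


class TestOATScan:
    def test_mff_total_monotone(self, table1):
        """Cumulative TF increases monotonically with the total Mff pool."""
        res = oat_scan(table1, "M_total")
        values = [res.cumulative[m] for m in res.multipliers]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_small_k_plus_shuts_down_fission(self, table1):
        res = oat_scan(table1, "k_plus", multipliers=(0.25, 1.0))
        baseline_peak = res.trajectories[1.0].tfr.max()
        assert res.trajectories[0.25].tfr.max() < 0.1 * baseline_peak

    def test_mu_classes_bracket_bifurcation(self, canonical):
        """mu multipliers {0.25,0.75,1} stay damped; {1.25,1.75} sustain."""
        res = oat_scan(canonical, "mu")
        assert [res.oscillation[m] for m in res.multipliers] == [
            "damped", "damped", "damped", "sustained", "sustained"]

    def test_baseline_required(self, table1):
        with pytest.raises(ValueError):
            oat_scan(table1, "k_plus", multipliers=(0.5, 1.5))

    def test_unknown_parameter(self, table1):
        with pytest.raises(ValueError):
            oat_scan(table1, "k_best")
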