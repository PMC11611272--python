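"""The mass-action right-hand side, its Jacobian and the conservation laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitofission import (
    DimensionalParams,
    StateVector,
    conserved_quantities,
    fission_rate,
    jacobian_dimensional,
    rhs_dimensional,
    validate_state,
)

from conftest import stoichiometry_rhs


class TestFissionRate:
    @pytest.mark.parametrize(
        "i,expected",
        [(1, 0.0), (25, 0.0), (26, 5.0), (30, 5.0)],
    )
    def test_step_values(self, table1, i, expected):
        assert fission_rate(i, table1) == expected

    @pytest.mark.parametrize("i", [0, 31, -3])
    def test_out_of_range(self, table1, i):
        with pytest.raises(ValueError):
            fission_rate(i, table1)

    def test_step_function_shape(self, table1):
        """Monotone nondecreasing in size, taking exactly the values {0, a}."""
        rates = [fission_rate(i, table1) for i in range(1, 31)]
        assert set(rates) == {0.0, table1.a}
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        assert rates[: table1.ell].count(0.0) == table1.ell

    def test_generic_threshold(self):
        p = DimensionalParams(ell=3, N_max=8, a=2.5)
        assert fission_rate(3, p) == 0.0
        assert fission_rate(4, p) == 2.5


class TestRHS:
    def test_initial_pool_state(self, table1):
        """With no oligomers only the binding flux k1*T*M is active."""
        u = np.zeros(32)
        u[0], u[1] = 20.0, 15.0
        du = rhs_dimensional(u, table1)
        assert du[0] == pytest.approx(-30.0)   # gamma * k1 * T * M
        assert du[1] == pytest.approx(-300.0)
        assert du[2] == pytest.approx(300.0)
        assert np.all(du[3:] == 0.0)

    def test_empty_membrane_is_fixed_point(self, table1):
        """T = 0 and C = 0 annihilates every reaction term."""
        u = np.zeros(32)
        u[1] = 7.0
        assert np.all(rhs_dimensional(u, table1) == 0.0)

    def test_matches_stoichiometry_oracle(self, table1, rng):
        """Vectorized kernel vs reaction-by-reaction assembly, random states."""
        for _ in range(100):
            u = rng.uniform(0.0, 2.0, 32)
            got = rhs_dimensional(u, table1)
            want = stoichiometry_rhs(u, table1)
            np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-12)

    def test_oracle_on_random_parameters(self, rng):
        for _ in range(20):
            p = DimensionalParams(
                k1=rng.uniform(0.1, 5), k_m1=rng.uniform(0.01, 1),
                k_plus=rng.uniform(0.1, 10), k_minus=rng.uniform(0.01, 1),
                a=rng.uniform(0.1, 10), gamma=rng.uniform(0.01, 1),
                T_total=rng.uniform(1, 40), M_total=rng.uniform(1, 40),
                ell=int(rng.integers(1, 28)), N_max=30,
            )
            u = rng.uniform(0.0, 2.0, 32)
            np.testing.assert_allclose(
                rhs_dimensional(u, p), stoichiometry_rhs(u, p),
                rtol=1e-10, atol=1e-12,
            )

    def test_mff_budget_identity(self, table1, rng):
        """d/dt(M + sum_i i*C_i) vanishes identically at any state."""
        weights = np.arange(1, 31)
        for _ in range(100):
            u = rng.uniform(0.0, 3.0, 32)
            du = rhs_dimensional(u, table1)
            assert du[1] + weights @ du[2:] == pytest.approx(0.0, abs=1e-10)

    def test_drp1_budget_identity(self, table1, rng):
        """d/dt(T + gamma * sum_i i*C_i) vanishes identically."""
        weights = np.arange(1, 31)
        for _ in range(50):
            u = rng.uniform(0.0, 3.0, 32)
            du = rhs_dimensional(u, table1)
            assert du[0] + table1.gamma * (weights @ du[2:]) == \
                pytest.approx(0.0, abs=1e-10)

    def test_shape_mismatch(self, table1):
        with pytest.raises(ValueError):
            rhs_dimensional(np.zeros(12), table1)


class TestJacobian:
    def test_finite_difference_agreement(self, table1, rng):
        eps = 1e-6
        for _ in range(20):
            u = rng.uniform(0.01, 2.0, 32)
            J = jacobian_dimensional(u, table1)
            Jfd = np.empty_like(J)
            for j in range(32):
                e = np.zeros(32)
                e[j] = eps
                Jfd[:, j] = (rhs_dimensional(u + e, table1)
                             - rhs_dimensional(u - e, table1)) / (2 * eps)
            np.testing.assert_allclose(J, Jfd, rtol=1e-6, atol=1e-6)

    def test_conservation_left_null_vectors(self, table1, rng):
        """The conservation weights annihilate the Jacobian at every state."""
        i_arr = np.arange(1.0, 31.0)
        w = np.concatenate(([1.0 / table1.gamma, 0.0], i_arr))
        v = np.concatenate(([0.0, 1.0], i_arr))
        for _ in range(20):
            u = rng.uniform(0.0, 3.0, 32)
            J = jacobian_dimensional(u, table1)
            np.testing.assert_allclose(w @ J, 0.0, atol=1e-12)
            np.testing.assert_allclose(v @ J, 0.0, atol=1e-12)


class TestConservedQuantities:
    def test_initial_state_totals(self, table1):
        u = np.zeros(32)
        u[0], u[1] = 20.0, 15.0
        assert conserved_quantities(u, table1) == pytest.approx((20.0, 15.0))

    def test_single_complex(self, table1):
        u = np.zeros(32)
        u[2] = 1.0
        t_cons, m_cons = conserved_quantities(u, table1)
        assert t_cons == pytest.approx(0.1)
        assert m_cons == pytest.approx(1.0)


class TestStateVector:
    def test_round_trip(self, rng):
        u = rng.uniform(0, 1, 32)
        sv = StateVector.from_array(u)
        np.testing.assert_allclose(sv.to_array(), u)
        assert sv.T == u[0] and sv.M == u[1]

    def test_validate_state(self):
        validate_state(np.full(32, -1e-10))
        with pytest.raises(ValueError):
            validate_state(np.array([1.0, -1e-6, 0.0]))


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    i=st.integers(min_value=1, max_value=30),
    a=st.floats(min_value=1e-3, max_value=100.0),
    ell=st.integers(min_value=1, max_value=29),
)
def test_fission_rate_two_valued(i, a, ell):
    """For any threshold the rate is 0 at or below it and a above it."""
    p = DimensionalParams(a=a, ell=ell, N_max=30)
    r = fission_rate(i, p)
    assert r == (a if i > ell else 0.0)
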