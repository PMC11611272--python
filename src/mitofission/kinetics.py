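"""Mass-action right-hand side, Jacobian and conserved quantities.

State layout (length ``N_max + 2``)::

    u[0] = T   (or z in the dimensionless system)
    u[1] = M   (or y)
    u[2 + j] = C_{j+1}, j = 0..N_max-1   (or x_{j+1})

The reaction network: cytosolic Drp1 tetramers T bind unbound membrane Mff
(k1 / k_m1) to form size-1 complexes C1; oligomers grow and shrink one
complex at a time (k_plus / k_minus, size-independent); oligomers longer
than the threshold ``ell`` trigger fission at rate ``a``, instantly
returning their i Drp1 and i Mff units to the free pools. The Drp1 balance
carries the compartment factor gamma (membrane/cytosol effective-space
ratio).

The dimensionless system is the same kernel evaluated at
(k1, k_m1, k_plus, k_minus, a, M_total) -> (beta, zeta, mu, 1, alpha, 1),
which is exactly the substitution z = T/M_total, y = M/M_total,
x_i = C_i/M_total, eta = k_minus * t.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .params import DimensionalParams, DimensionlessParams

__all__ = [
    "StateVector",
    "fission_rate",
    "rhs_dimensional",
    "rhs_dimensionless",
    "jacobian_dimensional",
    "jacobian_dimensionless",
    "conserved_quantities",
    "conserved_dimensionless",
    "validate_state",
]


class StateVector(NamedTuple):
    """Named view of a model state: free Drp1 pool, free Mff pool, oligomers.

    In the dimensionless system the same slots hold (z, y, x).
    """

    T: float
    M: float
    C: np.ndarray

    @classmethod
    def from_array(cls, u: np.ndarray) -> "StateVector":
        u = np.asarray(u, dtype=float)
        return cls(T=float(u[0]), M=float(u[1]), C=u[2:].copy())

    def to_array(self) -> np.ndarray:
        return np.concatenate(([self.T, self.M], np.asarray(self.C, float)))


def _as_array(state) -> np.ndarray:
    if isinstance(state, StateVector):
        return state.to_array()
    return np.asarray(state, dtype=float)


def fission_rate(i: int, params) -> float:
    """Size-dependent fission rate f(i): 0 up to the threshold, ``a`` above.

    ``a`` is read from dimensional params; for dimensionless params the
    corresponding group is alpha. Step function: f(i) = 0 for i <= ell,
    f(i) = a for ell < i <= N_max.
    """
    n = params.N_max
    if not 1 <= i <= n:
        raise ValueError(f"oligomer size {i} outside [1, {n}]")
    rate = params.a if isinstance(params, DimensionalParams) else params.alpha
    return rate if i > params.ell else 0.0


def _rhs_core(u, k1, km1, kp, km, a, gamma, ell, n):
    T = u[0]
    M = u[1]
    C = u[2:]
    C1 = C[0]
    i_arr = np.arange(1, n + 1)

    # fission return flux: a * sum_{i>ell} i*C_i
    fission_return = a * float(i_arr[ell:] @ C[ell:])
    bind = k1 * T * M
    core = km1 * C1 - bind + fission_return

    du = np.empty(n + 2)
    du[0] = gamma * core
    du[1] = core

    dC = du[2:]
    # C1: gains from binding and from every shrink event (2 when C2 splits),
    # loses to unbinding and to every elongation (2 when two C1 fuse).
    dC[0] = (
        bind
        - km1 * C1
        + km * (2.0 * C[1] + C[2:].sum())
        - kp * (2.0 * C1 * C1 + C[1 : n - 1].sum() * C1)
    )
    # interior sizes 2..n-1
    mid = C[1 : n - 1]
    loss = np.where(i_arr[1 : n - 1] > ell, a, 0.0)
    dC[1 : n - 1] = (
        -kp * C1 * (mid - C[0 : n - 2]) + km * (C[2:n] - mid) - loss * mid
    )
    # cap size n: no further growth; shrinks and (since ell < n) fissions
    dC[n - 1] = kp * C[n - 2] * C1 - (km + a) * C[n - 1]
    return du


def _dimless_coeffs(p: DimensionlessParams):
    return p.beta, p.zeta, p.mu, 1.0, p.alpha, p.gamma, p.ell, p.N_max


def rhs_dimensional(state, params: DimensionalParams) -> np.ndarray:
    """Time derivative (nM/s) of (T, M, C1..C_N) under mass action."""
    u = _as_array(state)
    if u.shape != (params.N_max + 2,):
        raise ValueError(
            f"state length {u.shape} incompatible with N_max={params.N_max}"
        )
    return _rhs_core(
        u, params.k1, params.k_m1, params.k_plus, params.k_minus,
        params.a, params.gamma, params.ell, params.N_max,
    )


def rhs_dimensionless(state, params: DimensionlessParams) -> np.ndarray:
    """Derivative of (z, y, x1..x_N) with respect to scaled time eta."""
    u = _as_array(state)
    if u.shape != (params.N_max + 2,):
        raise ValueError(
            f"state length {u.shape} incompatible with N_max={params.N_max}"
        )
    return _rhs_core(u, *_dimless_coeffs(params))


def _jac_core(u, k1, km1, kp, km, a, gamma, ell, n):
    T = u[0]
    M = u[1]
    C = u[2:]
    C1 = C[0]
    i_arr = np.arange(1, n + 1)
    J = np.zeros((n + 2, n + 2))

    # d(core)/du where core = km1*C1 - k1*T*M + a*sum_{i>ell} i*C_i
    row = np.zeros(n + 2)
    row[0] = -k1 * M
    row[1] = -k1 * T
    row[2] = km1
    row[2 + ell :] = a * i_arr[ell:]
    J[0] = gamma * row
    J[1] = row

    # C1 row
    r = J[2]
    r[0] = k1 * M
    r[1] = k1 * T
    r[2] = -km1 - kp * (4.0 * C1 + C[1 : n - 1].sum())
    r[3] = 2.0 * km - kp * C1
    r[4 : 2 + n - 1] = km - kp * C1  # sizes 3..n-1
    r[2 + n - 1] = km

    # interior rows, sizes i = 2..n-1 (state column of C_j is 2+j-1)
    for i in range(2, n):
        r = J[2 + i - 1]
        fi = a if i > ell else 0.0
        r[2] += -kp * (C[i - 1] - C[i - 2])      # via the common C1 factor
        r[2 + i - 2] += kp * C1                   # growth from C_{i-1}
        r[2 + i - 1] += -kp * C1 - km - fi        # self
        r[2 + i] += km                            # shrink of C_{i+1}

    # cap row
    r = J[2 + n - 1]
    r[2] += kp * C[n - 2]
    r[2 + n - 2] += kp * C1
    r[2 + n - 1] += -(km + a)
    return J


def jacobian_dimensional(state, params: DimensionalParams) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs_dimensional` (shape (N+2, N+2))."""
    u = _as_array(state)
    return _jac_core(
        u, params.k1, params.k_m1, params.k_plus, params.k_minus,
        params.a, params.gamma, params.ell, params.N_max,
    )


def jacobian_dimensionless(state, params: DimensionlessParams) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs_dimensionless`."""
    u = _as_array(state)
    return _jac_core(u, *_dimless_coeffs(params))


def conserved_quantities(state, params: DimensionalParams) -> tuple[float, float]:
    """Total Drp1 and total Mff implied by a state.

    T_cons = T + gamma * sum_i i*C_i,  M_cons = M + sum_i i*C_i.
    Both are constants of motion of the mass-action system.
    """
    u = _as_array(state)
    weighted = float(np.arange(1, params.N_max + 1) @ u[2:])
    return u[0] + params.gamma * weighted, u[1] + weighted


def conserved_dimensionless(state, params: DimensionlessParams) -> tuple[float, float]:
    """Dimensionless conserved pair (z + gamma*sum i*x_i, y + sum i*x_i).

    Equals (theta, 1) on any trajectory from the standard initial condition.
    """
    u = _as_array(state)
    weighted = float(np.arange(1, params.N_max + 1) @ u[2:])
    return u[0] + params.gamma * weighted, u[1] + weighted


def validate_state(state, tol: float = 1e-9) -> None:
    """Raise if any component is below ``-tol`` (solver negativity guard)."""
    u = _as_array(state)
    worst = u.min()
    if worst < -tol:
        raise ValueError(
            f"state has component {worst:.3e} below -{tol:.1e}; "
            "tighten solver tolerances"
        )
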