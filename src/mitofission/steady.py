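"""Fixed points, eigenvalue stability and the Hopf-bifurcation scan in mu.

The dimensionless system has two conserved quantities, so its Jacobian is
structurally rank-deficient: every fixed point carries two zero
eigenvalues whose left null-vectors are the conservation weights. Newton
iteration therefore runs on the reduced system with the free pools (z, y)
eliminated through the conservation constraints, giving a square
nonsingular problem in the oligomer concentrations alone; the full
Jacobian is used afterwards for the eigenvalue analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .kinetics import (
    conserved_dimensionless,
    jacobian_dimensionless,
    rhs_dimensionless,
)
from .params import DimensionlessParams
from .simulate import OscillationThresholds, classify_oscillation, simulate

__all__ = [
    "SteadyStateResult",
    "BifurcationPoint",
    "SteadyStateError",
    "find_steady_state",
    "eigen_stability",
    "bifurcation_scan",
    "find_hopf_mu",
]

#: eigenvalues with modulus below this are attributed to the conservation laws
ZERO_EIGENVALUE_TOL = 1e-8


class SteadyStateError(RuntimeError):
    """Newton failed to converge or hit a singular iteration matrix."""


@dataclass
class SteadyStateResult:
    """A converged fixed point with its spectrum and stability class."""

    fixed_point: np.ndarray
    residual_norm: float
    eigenvalues: np.ndarray = field(default=None)
    n_zero: int = 0
    max_re_nonzero: float = np.nan
    stable: bool = False
    n_iter: int = 0
    params: DimensionlessParams = None

    @property
    def tfr(self) -> float:
        """Dimensionless TFR evaluated at the fixed point."""
        p = self.params
        return p.alpha * float(self.fixed_point[2 + p.ell :].sum())


@dataclass(frozen=True)
class BifurcationPoint:
    """One mu value of the bifurcation diagram."""

    mu: float
    tfr_fixed: float
    tfr_max: float
    tfr_min: float
    stable: bool
    max_re_nonzero: float
    oscillation: str


def _reduced_residual_and_jac(x, params, z_target, y_target):
    n = params.N_max
    i_arr = np.arange(1.0, n + 1.0)
    w = float(i_arr @ x)
    u = np.empty(n + 2)
    u[0] = z_target - params.gamma * w
    u[1] = y_target - w
    u[2:] = x
    r = rhs_dimensionless(u, params)[2:]
    J = jacobian_dimensionless(u, params)
    # chain rule: z and y are affine functions of x on the manifold
    Jred = (
        J[2:, 2:]
        - np.outer(J[2:, 0], params.gamma * i_arr)
        - np.outer(J[2:, 1], i_arr)
    )
    return u, r, Jred


def find_steady_state(
    params: DimensionlessParams,
    guess: Optional[np.ndarray] = None,
    tol: float = 1e-11,
    max_iter: int = 200,
) -> SteadyStateResult:
    """Newton iteration for a fixed point of the dimensionless system.

    The iteration runs on the conservation manifold through ``guess``
    (default: the terminal state of a standard-horizon simulation, which
    for a stable fixed point is already close). Damped steps (backtracking
    on the residual norm) guard against the poor conditioning that appears
    once the fixed point loses stability. Convergence is declared when the
    sup-norm of the full right-hand side drops to ``tol``.
    """
    if guess is None:
        guess = simulate(params).states[-1]
    guess = np.asarray(guess, float)
    z_target, y_target = conserved_dimensionless(guess, params)
    x = guess[2:].copy()

    u, r, J = _reduced_residual_and_jac(x, params, z_target, y_target)
    rn = float(np.abs(r).max())
    for it in range(1, max_iter + 1):
        full_res = float(np.abs(rhs_dimensionless(u, params)).max())
        if full_res <= tol:
            return SteadyStateResult(
                fixed_point=u, residual_norm=full_res, n_iter=it - 1,
                params=params,
            )
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError as exc:
            raise SteadyStateError(
                f"singular Newton matrix at iteration {it} "
                f"(residual {rn:.3e})"
            ) from exc
        lam = 1.0
        for _ in range(40):
            x_new = x + lam * step
            u_new, r_new, J_new = _reduced_residual_and_jac(
                x_new, params, z_target, y_target
            )
            rn_new = float(np.abs(r_new).max())
            if rn_new < rn:
                break
            lam *= 0.5
        else:
            raise SteadyStateError(
                f"line search stalled at iteration {it} (residual {rn:.3e})"
            )
        x, u, r, J, rn = x_new, u_new, r_new, J_new, rn_new
    raise SteadyStateError(
        f"Newton did not reach tol={tol:.1e} in {max_iter} iterations "
        f"(last residual {rn:.3e})"
    )


def eigen_stability(
    result: SteadyStateResult,
    zero_tol: float = ZERO_EIGENVALUE_TOL,
) -> SteadyStateResult:
    """Attach the full spectrum and stability class to a fixed point.

    Two eigenvalues of modulus below ``zero_tol`` belong to the conserved
    quantities; stability is read off the largest real part of the
    remaining spectrum.
    """
    J = jacobian_dimensionless(result.fixed_point, result.params)
    eig = np.linalg.eigvals(J)
    zero_mask = np.abs(eig) < zero_tol
    result.eigenvalues = eig
    result.n_zero = int(zero_mask.sum())
    nonzero = eig[~zero_mask]
    result.max_re_nonzero = float(nonzero.real.max()) if nonzero.size else np.nan
    result.stable = result.max_re_nonzero < 0
    return result


def steady_state_with_stability(
    params: DimensionlessParams,
    guess: Optional[np.ndarray] = None,
    tol: float = 1e-11,
) -> SteadyStateResult:
    """Convenience: Newton solve followed by the eigenvalue analysis."""
    return eigen_stability(find_steady_state(params, guess=guess, tol=tol))


def bifurcation_scan(
    mu_grid: Sequence[float],
    base_params: Optional[DimensionlessParams] = None,
    *,
    t_end: float = 500.0,
    late_fraction: float = 0.2,
    thresholds: OscillationThresholds = OscillationThresholds(),
) -> list[BifurcationPoint]:
    """Fixed point, stability and simulated TFR envelope over a mu grid.

    Per mu (other dimensionless groups held at their canonical values): the
    fixed-point TFR (dashed branch of the diagram) and the late-window
    max/min of the simulated TFR, which coincide with the fixed-point value
    while it is stable and straddle it after the Hopf onset. Fixed points
    are warm-started by continuation from the previous grid point.
    """
    if base_params is None:
        base_params = DimensionlessParams()
    points = []
    prev_fp = None
    for mu in mu_grid:
        p = base_params.replace(mu=float(mu))
        traj = simulate(p, t_end)
        guess = prev_fp if prev_fp is not None else traj.states[-1]
        try:
            res = steady_state_with_stability(p, guess=guess)
        except SteadyStateError:
            res = steady_state_with_stability(p, guess=traj.states[-1])
        prev_fp = res.fixed_point
        n_late = max(int(len(traj.times) * late_fraction), 10)
        late_tfr = traj.tfr[-n_late:]
        points.append(
            BifurcationPoint(
                mu=float(mu),
                tfr_fixed=res.tfr,
                tfr_max=float(late_tfr.max()),
                tfr_min=float(late_tfr.min()),
                stable=res.stable,
                max_re_nonzero=res.max_re_nonzero,
                oscillation=classify_oscillation(traj, thresholds),
            )
        )
    return points


def find_hopf_mu(
    mu_lo: float = 750.0,
    mu_hi: float = 937.5,
    base_params: Optional[DimensionlessParams] = None,
    tol: float = 0.5,
) -> float:
    """Bisect on the sign of the leading nonzero eigenvalue's real part.

    ``mu_lo`` must give a stable fixed point and ``mu_hi`` an unstable one;
    returns the Hopf point mu* to within ``tol``.
    """
    if base_params is None:
        base_params = DimensionlessParams()

    def leading_re(mu, guess=None):
        p = base_params.replace(mu=mu)
        res = steady_state_with_stability(p, guess=guess)
        return res.max_re_nonzero, res.fixed_point

    re_lo, fp = leading_re(mu_lo)
    re_hi, _ = leading_re(mu_hi, guess=fp)
    if not (re_lo < 0 < re_hi):
        raise ValueError(
            f"bracket does not straddle the bifurcation: "
            f"Re(lo)={re_lo:.3e}, Re(hi)={re_hi:.3e}"
        )
    while mu_hi - mu_lo > tol:
        mid = 0.5 * (mu_lo + mu_hi)
        re_mid, fp = leading_re(mid, guess=fp)
        if re_mid < 0:
            mu_lo = mid
        else:
            mu_hi = mid
    return 0.5 * (mu_lo + mu_hi)
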