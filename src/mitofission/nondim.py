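"""Rescaling maps between the dimensional and dimensionless systems.

Concentrations are scaled by the total Mff pool and time by the oligomer
shrinkage rate: z = T/M_total, y = M/M_total, x_i = C_i/M_total,
eta = k_minus * t. Under this map a dimensional trajectory at rate
constants (k1, k_m1, k_plus, k_minus, a) coincides pointwise with the
dimensionless trajectory at (beta, zeta, mu, 1, alpha) — the central
correctness check of the rescaling (see tests).
"""

from __future__ import annotations

import numpy as np

from .params import DimensionalParams, DimensionlessParams, nondimensionalize
from .simulate import Trajectory

__all__ = [
    "nondimensionalize",
    "rescale_state",
    "restore_state",
    "rescale_trajectory",
]


def rescale_state(state: np.ndarray, params: DimensionalParams) -> np.ndarray:
    """Map a dimensional state (T, M, C) to dimensionless (z, y, x)."""
    return np.asarray(state, float) / params.M_total


def restore_state(state: np.ndarray, params: DimensionalParams) -> np.ndarray:
    """Inverse of :func:`rescale_state`."""
    return np.asarray(state, float) * params.M_total


def rescale_trajectory(traj: Trajectory) -> Trajectory:
    """Express a dimensional trajectory in dimensionless variables.

    Times map to eta = k_minus * t and every concentration divides by
    M_total; the attached parameter set becomes the corresponding
    :class:`DimensionlessParams`, so the derived TFR series is the
    dimensionless one (alpha * sum of fission-competent x_i).
    """
    p = traj.params
    if not isinstance(p, DimensionalParams):
        raise TypeError("rescale_trajectory expects a dimensional trajectory")
    return Trajectory(
        times=traj.times * p.k_minus,
        states=traj.states / p.M_total,
        params=nondimensionalize(p),
        solver_opts=dict(traj.solver_opts),
        nfev=traj.nfev,
    )
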