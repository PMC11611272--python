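"""Parameter containers for the Drp1/Mff fission model.

Two parameterizations are supported: the dimensional mass-action rate
constants (nM, s) and the dimensionless groups obtained by rescaling
concentrations by the total Mff pool ``M_total`` and time by the oligomer
dissociation rate ``k_minus``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

__all__ = [
    "DimensionalParams",
    "DimensionlessParams",
    "nondimensionalize",
]


def _positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class DimensionalParams:
    """Rate constants and totals of the dimensional fission model.

    Defaults are the canonical parameter set used throughout the analyses.

    Attributes
    ----------
    k1 : float
        Association rate of cytosolic Drp1 tetramers with unbound Mff,
        (nM s)^-1.
    k_m1 : float
        Dissociation rate of a Drp1-Mff complex back into T + M, s^-1.
    k_plus : float
        Elongation rate: a size-1 complex joining an oligomer, (nM s)^-1.
    k_minus : float
        Shrinkage rate: a size-1 complex leaving an oligomer, s^-1.
    a : float
        Fission rate of oligomers above the size threshold, s^-1.
    gamma : float
        Ratio of outer-membrane to cytosolic effective space (dimensionless).
    T_total : float
        Total tetrameric Drp1 concentration, nM.
    M_total : float
        Total Mff concentration, nM.
    ell : int
        Fission threshold: oligomers of size > ell can trigger fission.
    N_max : int
        Maximum oligomer size tracked.
    """

    k1: float = 1.0
    k_m1: float = 0.02
    k_plus: float = 5.0
    k_minus: float = 0.1
    a: float = 5.0
    gamma: float = 0.1
    T_total: float = 20.0
    M_total: float = 15.0
    ell: int = 25
    N_max: int = 30

    def __post_init__(self) -> None:
        # rates may sit at 0 (e.g. a=0 switches fission off; GSA ranges are
        # half-open at zero); totals and the compartment ratio must not.
        for f in ("k1", "k_m1", "k_plus", "k_minus", "a"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be nonnegative")
        for f in ("gamma", "T_total", "M_total"):
            _positive(f, getattr(self, f))
        if not (1 <= self.ell < self.N_max):
            raise ValueError(
                f"require 1 <= ell < N_max, got ell={self.ell}, "
                f"N_max={self.N_max}"
            )

    def replace(self, **kwargs) -> "DimensionalParams":
        return replace(self, **kwargs)

    def scaled(self, name: str, factor: float) -> "DimensionalParams":
        """Return a copy with one rate or total multiplied by ``factor``."""
        return self.replace(**{name: getattr(self, name) * factor})


@dataclass(frozen=True)
class DimensionlessParams:
    """Dimensionless groups of the rescaled fission model.

    mu = k_plus * M_total / k_minus is the maximum oligomer build rate over
    the disassembly rate; alpha = a / k_minus; beta = k1 * M_total / k_minus;
    zeta = k_m1 / k_minus; theta = T_total / M_total fixes the initial
    condition of the rescaled Drp1 pool. gamma, ell, N_max carry over
    unchanged. Defaults correspond to the canonical dimensional set.
    """

    mu: float = 750.0
    alpha: float = 50.0
    beta: float = 150.0
    zeta: float = 0.2
    gamma: float = 0.1
    theta: float = field(default=20.0 / 15.0)
    ell: int = 25
    N_max: int = 30

    def __post_init__(self) -> None:
        for f in ("mu", "alpha", "beta", "zeta"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be nonnegative")
        for f in ("gamma", "theta"):
            _positive(f, getattr(self, f))
        if not (1 <= self.ell < self.N_max):
            raise ValueError(
                f"require 1 <= ell < N_max, got ell={self.ell}, "
                f"N_max={self.N_max}"
            )

    def replace(self, **kwargs) -> "DimensionlessParams":
        return replace(self, **kwargs)

    def scaled(self, name: str, factor: float) -> "DimensionlessParams":
        return self.replace(**{name: getattr(self, name) * factor})


def nondimensionalize(params: DimensionalParams) -> DimensionlessParams:
    """Map dimensional rate constants onto the dimensionless groups.

    mu = k_plus*M_total/k_minus, alpha = a/k_minus, beta = k1*M_total/k_minus,
    zeta = k_m1/k_minus, theta = T_total/M_total; gamma, ell and N_max are
    carried over. The map is invariant under a common rescaling of all five
    rate constants (only ratios enter).
    """
    if params.k_minus <= 0:
        raise ZeroDivisionError(
            "nondimensionalization divides by k_minus; it must be positive"
        )
    return DimensionlessParams(
        mu=params.k_plus * params.M_total / params.k_minus,
        alpha=params.a / params.k_minus,
        beta=params.k1 * params.M_total / params.k_minus,
        zeta=params.k_m1 / params.k_minus,
        gamma=params.gamma,
        theta=params.T_total / params.M_total,
        ell=params.ell,
        N_max=params.N_max,
    )


def params_to_dict(params) -> dict:
    """Flat dict of parameter fields (for config round-trips and manifests)."""
    return {f.name: getattr(params, f.name) for f in fields(params)}
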