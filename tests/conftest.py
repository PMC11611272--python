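import numpy as np
import pytest

from mitofission import DimensionalParams, DimensionlessParams


@pytest.fixture
def table1():
    """Canonical dimensional parameter set."""
    return DimensionalParams()


@pytest.fixture
def canonical():
    """Canonical dimensionless parameter set (mu=750, alpha=50, ...)."""
    return DimensionlessParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def stoichiometry_rhs(u, p: DimensionalParams) -> np.ndarray:
    """Brute-force mass-action RHS assembled reaction-by-reaction.

    Independent oracle for the vectorized kernel: walks the reaction list
    (binding/unbinding, elongation/shrinkage at every size, fission above
    the threshold) and accumulates each reaction's stoichiometric
    contribution. Drp1-pool changes carry the compartment factor gamma.
    """
    n = p.N_max
    du = np.zeros(n + 2)

    def add(rate, changes):
        for idx, delta in changes:
            du[idx] += rate * delta * (p.gamma if idx == 0 else 1.0)

    T, M, C = u[0], u[1], u[2:]
    add(p.k1 * T * M, [(0, -1), (1, -1), (2, +1)])        # T + M -> C1
    add(p.k_m1 * C[0], [(0, +1), (1, +1), (2, -1)])       # C1 -> T + M
    for i in range(1, n):                                  # C_i + C1 <-> C_{i+1}
        add(p.k_plus * C[i - 1] * C[0],
            [(2 + i - 1, -1), (2, -1), (2 + i, +1)])
        add(p.k_minus * C[i], [(2 + i, -1), (2 + i - 1, +1), (2, +1)])
    for i in range(p.ell + 1, n + 1):                      # fission
        add(p.a * C[i - 1], [(2 + i - 1, -1), (0, +i), (1, +i)])
    return du
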