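"""Simulate the fission model at its canonical parameters.

Integrates the 32-state mass-action system (free Drp1 pool T, free Mff
pool M, oligomers C1..C30) over 5000 s from the all-unbound initial
condition, then reports the total fission rate (TFR) and its integral.
"""

from mitofission import (
    DimensionalParams,
    classify_oscillation,
    cumulative_tf,
    simulate,
)

params = DimensionalParams()  # canonical set: k+=5 (nM s)^-1, k-=0.1 s^-1, ...
traj = simulate(params, 5000.0)

print(f"peak TFR            : {traj.tfr.max():.4f} nM/s")
print(f"final TFR           : {traj.tfr[-1]:.4f} nM/s")
print(f"cumulative TF (5000s): {cumulative_tf(traj).value:.2f} nM")
print(f"oscillation class   : {classify_oscillation(traj)}")
print(f"conservation drift  : {traj.conservation_drift():.2e} (relative)")

# The TFR rings with damped oscillations — Mff returning to its unbound
# pool after each fission burst re-primes oligomer growth — and settles
# onto a steady state; the drift line confirms both protein budgets
# (total Drp1 and total Mff) are conserved by the integrator.
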