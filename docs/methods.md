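# Methods

## Model

The fission model is a closed mass-action reaction network on
(T, M, C₁…C_N): reversible Drp1–Mff binding (k₁, k₋₁), single-step oligomer
elongation/shrinkage with size-independent rates (k₊, k₋), and a
piecewise-constant fission rate f(i) = a·[i > ℓ] that removes an oligomer
and returns its i subunits to both free pools. The Drp1 equation carries the
compartment factor γ (membrane/cytosol effective-space ratio) because Drp1
crosses compartments while Mff and the oligomers live on the membrane. The
model is a common-pool description of a whole cell: no spatial structure, no
stochasticity, oligomer rates independent of size.

Two exact conservation laws follow from the network stoichiometry,
T + γΣᵢiCᵢ and M + ΣᵢiCᵢ. They are used three ways: as solver-quality
checks along trajectories, to eliminate (z, y) in the Newton solve, and to
explain the two structural zero eigenvalues of every Jacobian.

The fission threshold is applied as f(i) = a for all ℓ < i ≤ N including the
cap size N. This keeps the defining observable TFR = aΣᵢ₌ℓ₊₁^N Cᵢ consistent
with the cap equation Ċ_N = k₊C_{N−1}C₁ − (k₋ + a)C_N; an alternative
convention that exempts i = N from fission would let mass pile up at the cap
and change the observable. ℓ and N are free integers (defaults 25 and 30);
the qualitative dynamics are insensitive to them provided N is comfortably
above ℓ.

Canonical parameter values (defaults of `DimensionalParams`): k₁ = 1
(nM s)⁻¹, k₋₁ = 0.02 s⁻¹, k₊ = 5 (nM s)⁻¹, k₋ = 0.1 s⁻¹, a = 5 s⁻¹,
γ = 0.1, T̄ = 20 nM, M̄ = 15 nM. Rate constants may be zero (a = 0 switches
fission off; the GSA boxes are half-open at zero); totals, γ and θ must be
positive.

## Nondimensionalization

z = T/M̄, y = M/M̄, xᵢ = Cᵢ/M̄, η = k₋t gives groups μ = k₊M̄/k₋ (maximum
build rate over disassembly rate), α = a/k₋, β = k₁M̄/k₋, ζ = k₋₁/k₋, plus
θ = T̄/M̄ which is needed to place the initial condition (z, y) = (θ, 1) and
is therefore promoted to an explicit parameter. The dimensionless right-hand
side is obtained by substitution into the dimensional one — algebraically it
is the dimensional kernel evaluated at (k₁, k₋₁, k₊, k₋, a, M̄, T̄) =
(β, ζ, μ, 1, α, 1, θ) — so both systems share one code path and one analytic
Jacobian. The substitution is validated by the rescaling-equivalence test:
dimensional and dimensionless trajectories at independent numeric parameter
values agree pointwise to < 1e−5 sup-norm relative error after mapping.

## Numerics

* **Integration.** `solve_ivp` with LSODA and the analytic Jacobian;
  defaults rtol = 1e−8, atol = 1e−10, 2000 output points, horizons 5000 s
  (dimensional) / 500 η (dimensionless). The oligomer ladder is moderately
  stiff (k₊M̄ ≫ k₋); at these tolerances conservation drift is ~1e−14
  relative, far below the 1e−6 assertion. Nothing is clipped: the polynomial
  RHS is smooth, and a guard raises if any state drops below −1e−9
  (relative to scale).
* **Cumulative TF.** Trapezoid quadrature on the dense output grid with
  interpolated window endpoints. A second, error-controlled route appends
  d(TF)/dt = TFR to the state and reads the terminal value; it serves as
  the accuracy oracle and as the fast path in the GSA pipeline (only the
  endpoint is needed, so the GSA runs with t_eval at the endpoint alone and
  rtol = 1e−6, atol = 1e−9 — accurate to far better than the Monte-Carlo
  noise it feeds).
* **Newton fixed points.** The full 32-dim Jacobian is singular at any root
  (two conservation zeros), so Newton runs on the 30-dim reduced system with
  z and y eliminated through the conservation constraints of the initial
  guess; steps are damped by backtracking on the residual norm. Default
  guess: terminal state of a standard-horizon simulation; the bifurcation
  scan warm-starts each μ from the previous fixed point (continuation),
  which is what lets Newton converge to the *unstable* fixed point past the
  Hopf point. Convergence is declared at sup-norm residual ≤ 1e−11.
* **Eigen-classification.** Eigenvalues with |λ| < 1e−8 are attributed to
  the conserved quantities (tolerance chosen ≫ the Newton residual and ≪
  the slowest physical mode, whose magnitude is ~1e−2 at canonical
  parameters); stability is the sign of the largest remaining real part.
  The Hopf point μ* is located by bisection on that sign.

## Oscillation classing

The qualitative labels are operationalized as: **sustained** if the
last-20 %-window peak-to-trough TFR amplitude exceeds 5 % of the whole-run
mean TFR and consecutive late peaks decay < 10 %; **damped** if the late
amplitude has collapsed below that cutoff — including overdamped runs that
settle monotonically with no resolvable peaks (the low-μ regime);
**none** for negligible TFR throughout or a non-settling peakless series.
All thresholds live in `OscillationThresholds` and are overridable; they are
artifact choices, not measured quantities.

## Sensitivity analysis

**OAT.** Multipliers ×{0.25, 0.75, 1, 1.25, 1.75} on one parameter, others
fixed; outputs cumulative TF over the standard window plus the oscillation
class. Failures are recorded per multiplier without aborting the scan.

**Sobol GSA.** Cases: *case1* (k₁, k₋₁, k₊ ~ U(0,10), k₋ ~ U(0,1)); *case2*
(case1 plus M̄ ~ U(0,30)); *dimensionless* (μ, α, β, ζ each uniform on
(0, 2× canonical)). Parameters not varied stay at canonical values. The
Saltelli design is built from a scrambled Sobol' sequence in 2D dimensions
(scipy.stats.qmc): matrices A and B of base_N rows plus the hybrids AB_i and
BA_i, N(2D+2) model evaluations in total, base_N a power of two. Estimators
on standardized outputs: Saltelli-2010 for S1, Jansen for ST, and the
cross-block estimator V_ij/V − S1_i − S1_j for S2. 95 % CIs are percentile
bootstrap over base-design rows (default 1000 resamples, seeded); an index
is called significant when its CI excludes zero. Negative point estimates
(noise around zero) are reported as computed. The engine is validated
against closed-form decompositions of an additive function and the Ishigami
benchmark, independently of the ODE model.

Integration failures in a GSA row are retried at 100× tighter tolerance;
rows that still fail are imputed with the median of the successful outputs
(recorded in the result), and more than 1 % failures aborts the analysis —
silent imputation at scale would bias the indices. In practice no failures
occur over the standard boxes.

**Problem sizes.** The study-scale sample is base_N = 2048 (20,480 rows for
D = 4; 24,576 for D = 5). The bundled tests and the acceptance script use
the desk-scale base_N = 128, at which the Monte-Carlo standard error is
4× the study-scale one; reference bands are widened accordingly where the
tests compare against study-scale index values. Second-order indices are the
noisiest at desk scale.

## What the analyses show (and their limits)

All results are model-generated; there is no external data. The package's
tests demonstrate internal consistency (conservation, rescaling equivalence,
oracle agreement) and reproduce the model-level findings: the Hopf
bifurcation in μ with stable dynamics at and below the canonical μ = 750,
instability from μ* ≈ 827, and the concentration of cumulative-TF variance
onto μ (S1 ≈ ST ≈ 1). None of this validates the biological parameter
values themselves — the rate constants are order-of-magnitude choices, and
the model omits spatial structure, size-dependent kinetics, delayed Drp1
release and ER contact effects by construction.
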