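# Methods

## The reduction

We consider one-dimensional Langevin dynamics whose drift derives from a
potential that is linear in a vector of forces,

    dx = (g²(x)/2) d/dx[ s · α(t) · A(x) ] dt + g(x) dξ,

so that for constant forces the Fokker–Planck equation (FPE) has the
explicit stationary solution u_α(x) = ν(x) exp[s α·A(x)]/Z(α) with baseline
ν ∝ 1/g². The observable expectations evolve as

    d⟨A⟩/dt = B α + V/2,     B_ji = (s/2)⟨g² A_j′ A_i′⟩,   V_j = ⟨g² A_j″⟩,

a system that is not closed in general because B and V are expectations
under the unknown time-dependent density. The dynamic maximum-entropy (DME)
closure evaluates them under the stationary ansatz at effective forces
α*(t), chosen at every instant so that the ansatz's expectations track the
true ones. Using the stationarity identity B_{α*}α* + V_{α*}/2 = 0 and the
chain rule d⟨A⟩/dt = C dα*/dt with the sensitivity C = ∂⟨A⟩/∂α* = s·Cov(A),
this yields the closed ODE

    dα*/dt = C(α*)⁻¹ B(α*) (α(t) − α*).

Equivalently, α* maximizes the relative entropy −∫u log(u/u_α) of the true
density against the ansatz family; we report the error as the familiar
nonnegative KL divergence ∫u log(u/u_α*) ≥ 0. The maximizer matches the
observables exactly; concavity holds because the Hessian is −Cov(A) ⪯ 0.
The residual between the true density and the ansatz is neglected by the
closure and is quantified here only empirically, through the KL error of
the full pipeline.

Assumptions: one state dimension (the interfaces are deliberately
restricted to N = 1); an explicit exponential-family stationary form; a
constant noise scale (a smoothly time-varying σ(t) could be absorbed into a
time change, which we do not implement).

## Force parameterizations and the covariance scaling

Each model fixes the exponent scale s once and the engine works in the
coordinates that multiply s·A in the exponent:

* OU: A = (x, x²), α = (2μβ, −β), s = 1/σ₀². B, V, Cov and C have closed
  Gaussian forms; C = Cov/σ₀² and the reduction collapses to
  dμ*/dt = β(μ − μ*), dβ*/dt = 2β*(β − β*) — notably independent of σ₀.
* Island: A = (n, −n²/2, log n), α = (r, λ, m), s = 2 (the stationary
  exponent is 2α·A, so 2α are the Lagrange multipliers of the underlying
  maximum-entropy problem).

Whether C should be the plain covariance or the chain-rule-consistent
s·Cov is the one place where a constant factor changes the *speed* of the
transient without changing its fixed points. We resolve it empirically and
analytically in favour of C = s·Cov: it is the actual derivative
∂⟨A⟩/∂α*, it reduces to the closed-form OU sensitivity matrix, and in the
island step scenario it tracks the FPE mean within 0.1% where the plain
covariance (which doubles the relaxation rates) is off by tens of percent.
`island_matrices(..., scale_covariance=False)` exposes the other variant
for comparison. A consequence worth knowing: the slowest relaxation
eigenvalue of C⁻¹B at the island reference point (0.1, 0.002, 3) is
≈ 0.17/time, so the effective forces approach constant applied forces to
1e-6 only on a horizon of t ≈ 110, not within the first 50 time units.

## Island moment calculus

All stationary moments of the island model reduce to
G(k) = ∫₀^∞ n^{k+2m−1} e^{−λn²+2rn} dn (finite iff k + 2m > 0) and its
log-weighted companions H(k, j) = ∫ n^{k+2m−1}(log n)^j e^{…} dn.

* Production route: quadrature in u = log n, which removes the endpoint
  singularity and gives every integrand a proper interior maximum. The ODE
  right-hand side uses a vectorized composite Simpson rule (log-uniform
  step 0.02 through the power-law lower tail, switching to n-uniform with
  ~6000 nodes across the peak; the analytically known pure-power tail below
  u = −40 is added in closed form), memoized per force point. Spot
  accuracy against adaptive quadrature is ~1e-10 relative.
* Cross-check routes: the Kummer-function closed form
  G = ½λ^{−ν/2}Γ(ν/2)₁F₁(ν/2; ½; r²/λ) + rλ^{−(ν+1)/2}Γ((ν+1)/2)₁F₁((ν+1)/2; 3/2; r²/λ),
  ν = k + 2m, evaluated in 50-digit arithmetic when mpmath is available
  (double precision otherwise) — the hypergeometric argument r²/λ is
  moderate for the reference parameters but the series suffers cancellation
  for r < 0, which is why quadrature is authoritative; and
  H(k, j) = (1/2^j) ∂^j G/∂m^j by central finite differences, kept as a
  check because repeated m-differentiation is ill-conditioned.

Validity: the ansatz behaves as n^{2m−1} near n = 0, so ⟨1/n⟩ (an entry of
B) diverges for m ≤ 1/2 and the reduction fails. The package refuses such
forces with a diagnostic naming the diverging quantity; the boundary-layer
construction that would rescue m < 1/2 is out of scope.
`estimate_validity_threshold` localizes the frontier numerically (bisection
on lower-cutoff increments of the ⟨1/n⟩ integrand) to ~1e-5 of 1/2. Note
that G(−1) is not monotone in m far from the frontier — the n^{2m−2} peak
factor initially shrinks faster than the lower-tail divergence grows — so
the frontier is visible in cutoff sensitivity, not in raw magnitudes.

## Numerical choices

* **Effective-force ODE**: `solve_ivp` with LSODA (stiff-capable), defaults
  rtol 1e-8 / atol 1e-10. Drive protocols declare their discontinuity
  times and the integrator stops and restarts at each one; validity is
  re-checked inside the right-hand side and violations abort with the
  failure time.
* **Linear algebra**: C systems are solved by Cholesky with a
  symmetric-eigendecomposition fallback; eigenvalues negative at round-off
  level (≥ −1e-9 of the largest) are clipped, anything worse raises a
  conditioning error reporting the smallest eigenvalue.
* **Moment projection** (`project_to_forces`): matching ⟨A⟩ to a target is
  the stationarity condition of the strictly convex dual
  f(α) = log Z/s − α·target, so we first descend f by BFGS in unconstrained
  coordinates (log transforms of λ, m − 1/2, β) and then polish with damped
  Newton using the exact Jacobian C; scaled residual tolerance 1e-8.
* **Partition function and quadrature moments**: adaptive quadrature in log
  space (peak-subtracted), absolute tolerance 1e-12 / relative 1e-10;
  island integration domain (0, mode + 18·√(1/2λ)) with the grid's left
  edge placed at the 1e-10 mass quantile.
* **Density grids**: OU — linear over mean ± 10 sd; island — geometric
  spacing from the 1e-10 mass quantile to mode/3, then linear to
  mode + 15·√(1/2λ).
* **FPE solver**: cell-centered finite volume with Chang–Cooper
  (exponentially fitted) face weights and discrete zero-flux boundaries,
  BDF time stepping with an analytic tridiagonal Jacobian; 400 cells by
  default. The scheme's discrete stationary state satisfies
  u_{i+1}/u_i = exp(ã h/D) across every face, hence zero numerical flux at
  stationarity (verified to round-off) and second-order convergence to the
  analytic density (measured factor ≈ 4.0 per mesh doubling). Mass is
  monitored at every output time (tolerance 1e-6, typically conserved to
  1e-10); densities more negative than −1e-9 abort the run and round-off
  negatives are clipped on output. The island left boundary sits at a small
  n_lo > 0 where the analytic mass below is < 1e-10, avoiding the g² = n
  coordinate singularity.
* **Birth–death transition matrix**: rates b_n = m + n(1+r)/2,
  d_n = n(1−r)/2 + λn² (requires |r| ≤ 1). The split matches the SDE drift
  exactly; the jump variance m + n + λn² only approximates the diffusion's
  n, so pmf comparisons are held to total variation < 0.05 rather than
  exact agreement. Truncation at N_max with a tail-mass guard.
* **Euler–Maruyama**: default dt = 0.01 (drift·dt and per-step noise both
  small against typical state values for the reference parameters; halving
  dt moves ensemble means by less than one Monte-Carlo standard error at
  6000 paths). Island paths are reflected, n ← |n|, when a step overshoots
  below zero — the true m > 1/2 process never reaches 0, and reflection
  preserves the near-boundary stationary mass better than clamping, which
  would deposit an artificial atom at 0. Randomness: one SeedSequence child
  stream per trajectory (child 0 reserved for the initial-state sampler),
  so ensembles are bit-reproducible and grow without reshuffling.
* **KL between gridded densities**: both densities are interpolated onto
  the finer common grid and renormalized before integrating
  ∫u log(u/u_ref); nodes with u < 1e-15 contribute zero, and support
  mismatch (u appreciable where the reference vanishes) is an error naming
  the offending region.
* **Decay analysis**: after each drive switch, log KL is fitted from the
  post-switch KL maximum until the first 10× drop or the local minimum,
  whichever comes first; later increases above a 1e-12 floor raise the
  non-monotonicity flag.

## What the simulations emulate — and what they do not

The Euler–Maruyama ensembles and the synthetic scenarios (step changes,
square-wave and cosine-ramp periodic drives between carrying capacities 20
and 50, starting from the (0.05, 0.005, 1) equilibrium) are *in silico*
realizations of the two model SDEs, not of any empirical population. They
share the models' idealizations: demographic noise of fixed unit scale
(Poisson-offspring motivation), no age or spatial structure, no
environmental stochasticity beyond the prescribed deterministic drives, and
migration treated as a constant influx. Tests passing on these ensembles
show that the reduction, the PDE solver and the simulator agree *with each
other* about the model — they cannot show that the model describes any
particular real population. The smooth periodic drive's functional form is
a cosine-ramp interpolation between force levels (the ramp fraction is
configurable); other shapes are one line away in the config.

Problem sizes used throughout the examples and tests: 3000–6000 trajectories
at dt = 0.01, 200–1500 FPE cells, horizons of 40–120 time units, chosen so
the complete validation suite runs in a few minutes on a single core while
Monte-Carlo standard errors stay small against the effects being checked.

## Known limitations

* One state dimension only; the multivariate formalism is documented but
  not implemented.
* Island reduction refuses m ≤ 1/2 rather than correcting it (the
  boundary-layer treatment is future work); near the threshold the moment
  integrals become slow and ill-conditioned before they become invalid.
* The birth–death reference is drift-exact but variance-approximate, and
  any nonnegative drift-matching rate split is equally admissible — ours is
  one choice.
* Exactness of the reduction is special to the OU process (closed moment
  equations); for the island model the KL error is small but nonzero, and
  it relaxes non-monotonically after abrupt changes, which is why the error
  analysis fits only the early exponential window.
* The periodic-drive carrying capacities use λ ∈ {0.005, 0.002} (K = 20 and
  50); configurations with λ an order of magnitude smaller (K = 200, 500)
  are also valid inputs and ship as an alternative example config.
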