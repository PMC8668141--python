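# dmaxent

Dynamic maximum entropy (DME) reduction of one-dimensional stochastic
dynamics: replace a Fokker–Planck equation by a low-dimensional deterministic
ODE for *effective forces*, together with the full numerical stack needed to
judge how good that replacement is.

## The problem

Many stochastic models in population biology have an explicit stationary
distribution of exponential-family form,

```
u_α(x) = ν(x) · exp[ s · α · A(x) ] / Z(α),
```

with observables A(x), forces α, baseline ν(x) ∝ 1/g²(x) and a constant
exponent scale s. When the forces change in time — an environment that
shifts abruptly or oscillates with the seasons — the distribution is no
longer stationary and the full Fokker–Planck equation (FPE) must be solved.
DME instead tracks a time-indexed family of stationary-form densities
u_{α*(t)} whose effective forces obey the closed ODE

```
dα*/dt = C(α*)⁻¹ B(α*) (α(t) − α*),      C = s·Cov(A),   B = (s/2)·⟨g² A′ A′ᵀ⟩,
```

obtained by matching the observable expectations of the true dynamics with
those of the ansatz at every instant (a quasi-stationary moment closure).
The surprise that motivates this package: the closure stays extremely
accurate even when the forces jump abruptly, far outside the adiabatic
regime where it is obviously justified.

Two models are built in:

* **Ornstein–Uhlenbeck process** `dx = β(μ − x)dt + σ₀dξ`, observables
  A = (x, x²), forces α = (2μβ, −β), s = 1/σ₀². The moment equations close,
  so the reduction is *exact*: μ* and β* obey the decoupled system
  dμ*/dt = β(μ − μ*), dβ*/dt = 2β*(β − β*), independent of σ₀.
* **Stochastic logistic island model with immigration**
  `dn = [n(r − λn) + m]dt + √n dξ`, observables A = (n, −n²/2, log n),
  forces α = (r, λ, m), s = 2, carrying capacity K = r/λ. Here the closure
  is approximate, its moments reduce to confluent-hypergeometric integrals
  G(k) = ∫ n^{k+2m−1} e^{−λn²+2rn} dn, and it is valid only for strong
  migration m > 1/2 — below that, ⟨1/n⟩ in the matrix B diverges and the
  package refuses the regime with a diagnostic.

The validation stack: seeded Euler–Maruyama ensembles, a conservative
Chang–Cooper finite-volume FPE solver with no-flux boundaries, a
continuous-time birth–death transition-matrix method for the island model,
and relative-entropy (KL) error tracking with exponential-decay analysis.

## Worked example

An abrupt environmental improvement on the island: at t = 0 the forces jump
from (r, λ, m) = (0.05, 0.005, 1) — carrying capacity 10, weak migration —
to (0.1, 0.002, 3):

```python
import numpy as np
from dmaxent import integrate_effective_forces, DriveProtocol
from dmaxent.island import island_model, island_moments

model = island_model()
before = np.array([0.05, 0.005, 1.0])
after  = np.array([0.10, 0.002, 3.0])
times = np.array([0.0, 1.0, 5.0, 10.0, 40.0])
path = integrate_effective_forces(model, DriveProtocol.step(before, after),
                                  before, times)
for t, a in zip(times, path):
    mom = island_moments(a)
    print(f"{t:5.0f} {a[0]:8.4f} {a[1]:9.5f} {a[2]:7.3f} "
          f"{mom.n:8.2f} {mom.log_n:9.4f}")
```

prints

```
    0   0.0500   0.00500   1.000    17.77    2.7558
    1  -0.0072   0.00256   1.588    21.81    2.9823
    5  -0.0118   0.00124   2.386    37.44    3.5573
   10   0.0462   0.00156   2.190    52.35    3.9151
   40   0.1003   0.00200   2.962    68.83    4.2101
```

Each row is a point α*(t) in force space whose stationary density is the
DME estimate of the full population-size distribution at that time. The
mean population size ⟨n⟩ climbs smoothly from 17.8 towards its new
equilibrium near 68.8, while the effective forces themselves move
non-monotonically (r* first turns *negative*) — the low-dimensional
trajectory encodes a genuinely non-equilibrium distribution shape.
Running the same scenario through the FPE solver
(`dmaxent.experiments.run_step_experiment`) shows all three observables
agree with the reduction to a few parts in 10⁴ throughout the transient.

A command-line front end exposes the same pipelines
(`dmaxent ou`, `dmaxent island`, `dmaxent simulate`, `dmaxent fpe`,
`dmaxent compare`); see `examples/` for ready-made YAML configs and
`dmaxent --help` for flags. Every run writes CSVs plus a JSON manifest
recording parameters, seeds and tolerances.

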