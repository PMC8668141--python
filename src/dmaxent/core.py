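"""Generic dynamic maximum entropy (DME) engine.

The engine reduces 1D stochastic dynamics of the Langevin form

    dx = (g^2(x)/2) d/dx[ s * alpha(t) . A(x) ] dt + g(x) dxi(t)

to a d-dimensional deterministic ODE for "effective forces" alpha*(t).  The
stationary density for constant forces is the exponential family

    u_alpha(x) = nu(x) exp[ s * alpha . A(x) ] / Z(alpha),

with baseline nu(x) proportional to 1/g^2(x), observables A(x) and a constant
exponent scale s that fixes the model's force parameterization.  Matching the
observable expectations of the true (Fokker-Planck) solution with those of the
ansatz at every time yields the closed dynamics

    d(alpha*)/dt = C^{-1} B (alpha(t) - alpha*),

where B is the Gram matrix of observable gradients under the g^2-weighted
stationary density and C = s * Cov(A) is the sensitivity of the expectations
to the forces.  All of this module is model-agnostic: concrete models (the
Ornstein-Uhlenbeck process, the stochastic logistic island) plug in through a
:class:`ModelSpec`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import integrate, linalg

from .protocols import DriveProtocol

__all__ = [
    "ValidityError",
    "DomainError",
    "ConditioningError",
    "SupportMismatchError",
    "GriddedDensity",
    "MomentMatrices",
    "ModelSpec",
    "stationary_density",
    "log_partition",
    "moments_of",
    "expectations",
    "covariance_of",
    "moment_matrices",
    "relative_entropy_kl",
    "dme_rhs",
    "integrate_effective_forces",
    "project_to_forces",
]


class ValidityError(ValueError):
    """A force vector violates the model's validity constraints."""


class DomainError(ValueError):
    """An integral diverges or a quantity is requested outside its domain."""


class ConditioningError(np.linalg.LinAlgError):
    """The sensitivity matrix C is singular or indefinite."""


class SupportMismatchError(ValueError):
    """KL divergence requested where the reference density vanishes."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class GriddedDensity:
    """Probability density sampled on a strictly increasing 1D grid."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.values.shape:
            raise ValueError("grid and values must be 1D arrays of equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.values < -1e-12):
            raise ValueError("density values must be nonnegative")

    @property
    def mass(self) -> float:
        return float(np.trapezoid(self.values, self.grid))

    def normalized(self) -> "GriddedDensity":
        return GriddedDensity(self.grid, self.values / self.mass)

    def moment(self, func: Callable[[np.ndarray], np.ndarray]) -> float:
        return float(np.trapezoid(func(self.grid) * self.values, self.grid))

    def interp_to(self, grid: np.ndarray) -> "GriddedDensity":
        vals = np.interp(grid, self.grid, self.values, left=0.0, right=0.0)
        return GriddedDensity(grid, np.clip(vals, 0.0, None))


@dataclass
class MomentMatrices:
    """DME right-hand-side ingredients evaluated at one force point.

    ``B`` is the d x d Gram matrix (s/2)<g^2 A_j' A_i'>, ``V`` the d-vector
    <g^2 A_j''> (the moment ODE reads d<A>/dt = B alpha + V/2), ``Cov`` the
    observable covariance and ``C = s Cov`` the force-sensitivity matrix
    d<A>/d(alpha).
    """

    B: np.ndarray
    V: np.ndarray
    Cov: np.ndarray
    C: np.ndarray


@dataclass(frozen=True)
class ModelSpec:
    """Everything the generic engine needs to know about a concrete model.

    The force vector ``alpha`` lives in the model's natural parameterization:
    the stationary density is nu(x) * exp[s * alpha . A(x)] / Z.
    """

    name: str
    dim: int
    domain: tuple[float, float]
    observables: Callable[[np.ndarray], np.ndarray]        # x -> (d, n)
    observable_grad: Callable[[np.ndarray], np.ndarray]    # x -> (d, n)
    observable_lap: Callable[[np.ndarray], np.ndarray]     # x -> (d, n)
    noise_g2: Callable[[np.ndarray], np.ndarray]
    noise_g2_prime: Callable[[np.ndarray], np.ndarray]
    log_baseline: Callable[[np.ndarray], np.ndarray]
    force_scale: float
    validity: Callable[[np.ndarray], list[str]]            # -> violation messages
    quad_bounds: Callable[[np.ndarray], tuple[float, float, float]]  # lo, hi, mode
    default_grid: Callable[[np.ndarray, int], np.ndarray]
    matrices: Callable[[np.ndarray], MomentMatrices] | None = field(
        default=None, compare=False)
    # smooth bijection between the valid force region and R^d (log transforms
    # of positivity-constrained components); used to globalize projections
    to_unconstrained: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, compare=False)
    from_unconstrained: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, compare=False)

    def check_valid(self, alpha) -> None:
        violations = self.validity(np.asarray(alpha, dtype=float))
        if violations:
            raise ValidityError(
                f"invalid forces for model '{self.name}': " + "; ".join(violations))

    def log_unnormalized(self, alpha, x):
        """log of nu(x) exp[s alpha . A(x)] (no normalization)."""
        x = np.asarray(x, dtype=float)
        A = self.observables(x)
        return self.log_baseline(x) + self.force_scale * np.tensordot(
            np.asarray(alpha, float), A, axes=(0, 0))

    def drift(self, alpha, x):
        """SDE drift (g^2/2) d/dx [s alpha . A(x)]."""
        x = np.asarray(x, dtype=float)
        Ap = self.observable_grad(x)
        return 0.5 * self.noise_g2(x) * self.force_scale * np.tensordot(
            np.asarray(alpha, float), Ap, axes=(0, 0))


# --------------------------------------------------------------------------
# stationary densities, partition function, moments
# --------------------------------------------------------------------------

def _peak_log(model: ModelSpec, alpha) -> float:
    lo, hi, mode = model.quad_bounds(alpha)
    xs = np.linspace(lo, hi, 4001)
    scan = float(np.max(model.log_unnormalized(alpha, xs)))
    at_mode = float(model.log_unnormalized(alpha, np.array([mode]))[0])
    return max(scan, at_mode)


def log_partition(model: ModelSpec, alpha) -> float:
    """log Z(alpha), computed in log space by adaptive quadrature."""
    model.check_valid(alpha)
    lo, hi, mode = model.quad_bounds(alpha)
    peak = _peak_log(model, alpha)

    def f(x):
        return np.exp(model.log_unnormalized(alpha, x) - peak)

    val, _ = integrate.quad(f, lo, hi, points=[mode], limit=400,
                            epsabs=1e-12, epsrel=1e-10)
    if not np.isfinite(val) or val <= 0:
        raise DomainError(f"partition function diverged for alpha={alpha}")
    return peak + float(np.log(val))


def stationary_density(model: ModelSpec, alpha, grid: np.ndarray | None = None,
                       n_points: int = 2001) -> GriddedDensity:
    """Stationary (maximum-entropy) density on a grid, trapezoid-normalized."""
    model.check_valid(alpha)
    if grid is None:
        grid = model.default_grid(np.asarray(alpha, float), n_points)
    grid = np.asarray(grid, dtype=float)
    logu = model.log_unnormalized(alpha, grid)
    logu = logu - np.max(logu)
    vals = np.exp(logu)
    # estimate the mass the grid fails to cover (value ratios are misleading
    # for power-law edges like the island's n^{2m-1}); a local power-law
    # extrapolation u ~ x^p towards a finite edge integrates to u0*gap/(p+1)
    total = np.trapezoid(vals, grid)

    def _edge_mass(v0, v1, x0, x1, gap):
        if v0 <= 0:
            return 0.0
        if v1 > 0 and x0 > 0 and x1 > x0:
            p = (np.log(v1) - np.log(v0)) / (np.log(x1) - np.log(x0))
            if p > -0.9:
                return v0 * gap / (p + 1.0)
        return v0 * gap

    if np.isfinite(model.domain[0]):
        d0 = model.domain[0]
        left = _edge_mass(vals[0], vals[1], grid[0] - d0, grid[1] - d0,
                          grid[0] - d0)
    else:
        left = vals[0] * (grid[1] - grid[0])
    if np.isfinite(model.domain[1]):
        d1 = model.domain[1]
        right = _edge_mass(vals[-1], vals[-2], d1 - grid[-1], d1 - grid[-2],
                           d1 - grid[-1])
    else:
        right = vals[-1] * (grid[-1] - grid[-2])
    out_mass = (left + right) / total
    if out_mass > 1e-3:
        warnings.warn(
            f"stationary density leaks ~{out_mass:.2e} of its mass outside "
            "the grid; widen the grid", RuntimeWarning)
    dens = GriddedDensity(grid, vals).normalized()
    if abs(dens.mass - 1.0) > 1e-6:
        raise DomainError("density failed to normalize on the given grid")
    return dens


def expectations(model: ModelSpec, alpha,
                 funcs: Sequence[Callable[[np.ndarray], np.ndarray]]) -> np.ndarray:
    """Adaptive-quadrature expectations <f_k(x)> under the stationary density."""
    model.check_valid(alpha)
    lo, hi, mode = model.quad_bounds(alpha)
    peak = _peak_log(model, alpha)

    def weight(x):
        return np.exp(model.log_unnormalized(alpha, x) - peak)

    z, _ = integrate.quad(weight, lo, hi, points=[mode], limit=400,
                          epsabs=1e-12, epsrel=1e-10)
    out = np.empty(len(funcs))
    for k, f in enumerate(funcs):
        val, _ = integrate.quad(lambda x: f(np.atleast_1d(x))[0] * weight(x),
                                lo, hi, points=[mode], limit=400,
                                epsabs=1e-12, epsrel=1e-10)
        out[k] = val / z
    return out


def moments_of(model: ModelSpec, density_or_alpha) -> np.ndarray:
    """Observable expectations <A> under a gridded density or force point."""
    if isinstance(density_or_alpha, GriddedDensity):
        dens = density_or_alpha
        lo = dens.grid[0]
        # island-like domains: mass piling at the left edge makes <1/n>-type
        # quantities unreliable
        if lo > model.domain[0] and dens.values[0] * (dens.grid[1] - lo) > 1e-6:
            warnings.warn("non-negligible density mass at the left grid edge; "
                          "singular moments may be unreliable", RuntimeWarning)
        A = model.observables(dens.grid)
        return np.trapezoid(A * dens.values, dens.grid, axis=1)
    alpha = np.asarray(density_or_alpha, dtype=float)
    funcs = [lambda x, i=i: model.observables(x)[i] for i in range(model.dim)]
    return expectations(model, alpha, funcs)


def covariance_of(model: ModelSpec, alpha) -> np.ndarray:
    """Covariance matrix of the observables under the stationary density."""
    d = model.dim
    first = moments_of(model, alpha)
    cov = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            func = [lambda x, i=i, j=j: model.observables(x)[i] * model.observables(x)[j]]
            second = expectations(model, alpha, func)[0]
            cov[i, j] = cov[j, i] = second - first[i] * first[j]
    return cov


def moment_matrices(model: ModelSpec, alpha) -> MomentMatrices:
    """B, V, Cov and C = s Cov at a force point.

    Uses the model's specialized routine when provided (closed forms for the
    OU process, the hypergeometric moment calculus for the island model),
    falling back to direct quadrature.
    """
    alpha = np.asarray(alpha, dtype=float)
    if model.matrices is not None:
        return model.matrices(alpha)
    d, s = model.dim, model.force_scale
    B = np.empty((d, d))
    V = np.empty(d)
    for j in range(d):
        for i in range(j, d):
            f = [lambda x, i=i, j=j: model.noise_g2(x)
                 * model.observable_grad(x)[j] * model.observable_grad(x)[i]]
            B[j, i] = B[i, j] = 0.5 * s * expectations(model, alpha, f)[0]
        g = [lambda x, j=j: model.noise_g2(x) * model.observable_lap(x)[j]]
        V[j] = expectations(model, alpha, g)[0]
    Cov = covariance_of(model, alpha)
    return MomentMatrices(B=B, V=V, Cov=Cov, C=s * Cov)


# --------------------------------------------------------------------------
# relative entropy
# --------------------------------------------------------------------------

def relative_entropy_kl(u: GriddedDensity, u_ref: GriddedDensity,
                        support_tol: float = 1e-12) -> float:
    """KL divergence integral u log(u/u_ref) between gridded densities.

    The densities are interpolated onto the finer common grid.  Nodes where u
    is below 1e-15 contribute zero; nodes where u is appreciable but u_ref
    vanishes raise :class:`SupportMismatchError`.
    """
    if len(u.grid) >= len(u_ref.grid):
        grid = u.grid
    else:
        grid = u_ref.grid
    lo = max(u.grid[0], u_ref.grid[0])
    hi = min(u.grid[-1], u_ref.grid[-1])
    grid = grid[(grid >= lo) & (grid <= hi)]
    p = u.interp_to(grid).normalized().values
    q = u_ref.interp_to(grid).normalized().values

    bad = (p > support_tol) & (q < 1e-300)
    if np.any(bad):
        xs = grid[bad]
        raise SupportMismatchError(
            f"u has mass where the reference density vanishes "
            f"(x in [{xs.min():.4g}, {xs.max():.4g}])")
    active = p > 1e-15
    integrand = np.zeros_like(p)
    integrand[active] = p[active] * np.log(p[active] / q[active])
    val = float(np.trapezoid(integrand, grid))
    if val < -1e-10:
        warnings.warn(f"KL evaluated to {val:.2e} < 0; densities may be "
                      "under-resolved", RuntimeWarning)
    return val


# --------------------------------------------------------------------------
# the DME dynamical system
# --------------------------------------------------------------------------

def _solve_spd(C: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve C y = rhs for symmetric positive definite C (Cholesky, with a
    symmetric-eigendecomposition fallback)."""
    try:
        cho = linalg.cho_factor(C, lower=True)
        return linalg.cho_solve(cho, rhs)
    except linalg.LinAlgError:
        w, Q = linalg.eigh(C)
        if w[0] <= 0:
            if w[0] < -1e-9 * abs(w[-1]):
                raise ConditioningError(
                    f"sensitivity matrix C is not positive definite "
                    f"(smallest eigenvalue {w[0]:.3e})") from None
            # roundoff-level indefiniteness: clip to a tiny positive floor
            w = np.maximum(w, 1e-14 * abs(w[-1]))
        return Q @ ((Q.T @ rhs) / w)


def dme_rhs(model: ModelSpec, effective, applied,
            mats: MomentMatrices | None = None) -> np.ndarray:
    """Right-hand side of d(alpha*)/dt = C^{-1} B (alpha - alpha*).

    Solved as a linear system (never by explicit inversion).
    """
    effective = np.asarray(effective, dtype=float)
    applied = np.asarray(applied, dtype=float)
    model.check_valid(effective)
    if mats is None:
        mats = moment_matrices(model, effective)
    rhs = mats.B @ (applied - effective)
    return _solve_spd(mats.C, rhs)


def integrate_effective_forces(model: ModelSpec, protocol: DriveProtocol,
                               initial, times, rtol: float = 1e-8,
                               atol: float = 1e-10,
                               method: str = "LSODA") -> np.ndarray:
    """Integrate the effective-force ODE along a drive protocol.

    The integrator stops and restarts at every declared protocol switch time,
    so discontinuous applied forces never cross a live integration step.
    Returns an array of shape (len(times), d).  Raises
    :class:`ValidityError` annotated with the failure time if the path leaves
    the model's validity region.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be nondecreasing")
    initial = np.asarray(initial, dtype=float)
    model.check_valid(initial)

    current_t = float(times[0])

    def rhs(t, a):
        violations = model.validity(a)
        if violations:
            raise ValidityError(
                f"effective forces left the validity region at t={t:.6g}: "
                + "; ".join(violations))
        return dme_rhs(model, a, protocol(t))

    out = np.empty((len(times), model.dim))
    out[0] = initial
    state = initial.copy()
    seg_edges = [current_t] + protocol.switches_in(current_t, times[-1]) + [times[-1]]
    idx = 1
    for t0, t1 in zip(seg_edges[:-1], seg_edges[1:]):
        if t1 <= t0:
            continue
        eval_t = times[(times > t0) & (times <= t1)]
        sol = integrate.solve_ivp(rhs, (t0, t1), state, method=method,
                                  t_eval=None, dense_output=True,
                                  rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(
                f"effective-force integration failed on [{t0:.4g}, {t1:.4g}]: "
                + sol.message)
        for te in eval_t:
            out[idx] = sol.sol(te)
            idx += 1
        state = sol.y[:, -1]
    return out


def project_to_forces(model: ModelSpec, target, guess, tol: float = 1e-8,
                      maxiter: int = 50) -> np.ndarray:
    """Invert the moment map: find alpha* with <A>_{alpha*} = target.

    Newton iteration using the exact Jacobian C = s Cov; the step is damped
    (halved) whenever it would leave the validity region.
    """
    target = np.asarray(target, dtype=float)
    alpha = np.asarray(guess, dtype=float).copy()
    model.check_valid(alpha)
    scale = 1.0 + np.abs(target)
    s = model.force_scale

    # Matching moments is the stationarity condition of the strictly convex
    # dual objective f(alpha) = log Z(alpha)/s - alpha . target, whose
    # gradient is <A>_alpha - target and Hessian is C = s Cov > 0, so damped
    # Newton with an Armijo line search converges from any valid start.
    def objective(a):
        return log_partition(model, a) / s - float(a @ target)

    # globalization: descend the dual in unconstrained coordinates first, so
    # positivity constraints (lambda > 0, m > 1/2, beta > 0) cannot strangle
    # the line search far from the solution
    if model.to_unconstrained is not None:
        from scipy import optimize

        def f_and_g(z):
            a = model.from_unconstrained(z)
            grad_a = moments_of(model, a) - target
            eps = 1e-7
            jac = np.empty((model.dim, model.dim))
            for i in range(model.dim):
                zp = z.copy()
                zp[i] += eps
                jac[:, i] = (model.from_unconstrained(zp) - a) / eps
            return objective(a), jac.T @ grad_a

        res = optimize.minimize(f_and_g, model.to_unconstrained(alpha),
                                jac=True, method="BFGS",
                                options={"gtol": 1e-6, "maxiter": 200})
        cand = model.from_unconstrained(res.x)
        if not model.validity(cand):
            alpha = cand

    f_val = objective(alpha)
    for _ in range(maxiter):
        grad = moments_of(model, alpha) - target
        if np.max(np.abs(grad) / scale) < tol:
            return alpha
        mats = moment_matrices(model, alpha)
        step = _solve_spd(mats.C, -grad)
        slope = float(grad @ step)  # negative by positive definiteness
        lam = 1.0
        for _ in range(60):
            trial = alpha + lam * step
            if not model.validity(trial):
                f_trial = objective(trial)
                if f_trial <= f_val + 1e-4 * lam * slope:
                    break
            lam *= 0.5
        else:
            raise ValidityError(
                "projection cannot make progress inside the validity "
                "region; target may be outside the attainable moment cone")
        alpha, f_val = trial, f_trial
    grad = moments_of(model, alpha) - target
    raise RuntimeError(
        f"moment projection did not converge in {maxiter} iterations "
        f"(last scaled residual {np.max(np.abs(grad) / scale):.3e})")
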