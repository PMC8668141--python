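"""Ornstein-Uhlenbeck model: the exactness testbed for DME.

The process dx = beta(t) (mu(t) - x) dt + sigma0 dxi has observables
A = (x, x^2) and exponent-coordinate forces alpha = (2 mu beta, -beta) with
scale s = 1/sigma0^2, so the stationary density is the Gaussian
N(mu, sigma0^2 / (2 beta)).  Because the first two moment equations close,
the DME reduction is exact here: the effective forces obey the decoupled
system

    d(mu*)/dt  = beta(t) (mu(t) - mu*),
    d(beta*)/dt = 2 beta* (beta(t) - beta*),

independent of sigma0, and the reconstructed moments m = mu*,
v = sigma0^2/(2 beta*) coincide with the exact Gaussian solution for any
drive protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .core import ModelSpec, MomentMatrices, ValidityError
from .protocols import DriveProtocol

__all__ = [
    "OUParams",
    "GaussianState",
    "ou_model",
    "alpha_from_natural",
    "natural_from_alpha",
    "ou_matrices",
    "ou_exact_moments",
    "ou_closed_form_moments",
    "ou_dme_rhs",
    "ou_dme_solution",
]


# --------------------------------------------------------------------------
# parameterization
# --------------------------------------------------------------------------

def alpha_from_natural(mu: float, beta: float) -> np.ndarray:
    """(mu, beta) -> exponent coordinates alpha = (2 mu beta, -beta)."""
    return np.array([2.0 * mu * beta, -beta])


def natural_from_alpha(alpha) -> tuple[float, float]:
    a1, a2 = np.asarray(alpha, dtype=float)
    beta = -a2
    if beta <= 0:
        raise ValidityError(f"alpha={alpha} implies beta={beta} <= 0")
    return a1 / (2.0 * beta), beta


@dataclass(frozen=True)
class OUParams:
    """OU drive specification.

    ``protocol`` evaluates to the applied natural forces (mu(t), beta(t));
    ``sigma0`` is the constant noise magnitude; (mu0, beta0) define the
    stationary Gaussian N(mu0, sigma0^2/(2 beta0)) used as initial condition.
    """

    protocol: DriveProtocol
    sigma0: float
    mu0: float
    beta0: float

    def __post_init__(self):
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if self.beta0 <= 0:
            raise ValueError("beta0 must be positive")

    @classmethod
    def constant(cls, mu, beta, sigma0, mu0=None, beta0=None) -> "OUParams":
        proto = DriveProtocol.constant([mu, beta])
        return cls(proto, sigma0,
                   mu if mu0 is None else mu0,
                   beta if beta0 is None else beta0)

    @classmethod
    def step_change(cls, mu0, beta0, mu_inf, beta_inf, sigma0) -> "OUParams":
        """Stationary start at (mu0, beta0); forces jump to the new values at t=0."""
        proto = DriveProtocol.step([mu0, beta0], [mu_inf, beta_inf], t_switch=0.0)
        return cls(proto, sigma0, mu0, beta0)


@dataclass
class GaussianState:
    """Gaussian solution state N(m, v); (f, g, h) views of the same density."""

    m: float
    v: float

    def __post_init__(self):
        if self.v <= 0:
            raise ValueError("variance must be positive")

    @property
    def g(self) -> float:
        return 1.0 / (2.0 * self.v)

    @property
    def h(self) -> float:
        return self.m

    @property
    def f(self) -> float:
        # normalization of f * exp(-g (x - h)^2)
        return np.sqrt(self.g / np.pi)


# --------------------------------------------------------------------------
# ModelSpec for the generic engine
# --------------------------------------------------------------------------

def ou_matrices(mu_star: float, beta_star: float, sigma0: float) -> MomentMatrices:
    """Closed-form B, V, Cov and C = Cov/sigma0^2 at effective forces."""
    if beta_star <= 0:
        raise ValidityError(f"beta* must be positive, got {beta_star}")
    v = sigma0**2 / (2.0 * beta_star)
    B = np.array([[0.5, mu_star],
                  [mu_star, 2.0 * mu_star**2 + sigma0**2 / beta_star]])
    V = np.array([0.0, 2.0 * sigma0**2])
    Cov = np.array([[v, 2.0 * mu_star * v],
                    [2.0 * mu_star * v, 2.0 * v**2 + 4.0 * mu_star**2 * v]])
    return MomentMatrices(B=B, V=V, Cov=Cov, C=Cov / sigma0**2)


def ou_model(sigma0: float) -> ModelSpec:
    """Generic-engine specification of the OU model at fixed sigma0."""
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    s2 = float(sigma0) ** 2

    def observables(x):
        return np.stack([x, x * x])

    def observable_grad(x):
        return np.stack([np.ones_like(x), 2.0 * x])

    def observable_lap(x):
        return np.stack([np.zeros_like(x), 2.0 * np.ones_like(x)])

    def validity(alpha):
        out = []
        if not np.all(np.isfinite(alpha)):
            out.append("non-finite force entries")
        elif alpha[1] >= 0:
            out.append(f"beta = {-alpha[1]} must be positive")
        return out

    def quad_bounds(alpha):
        mu, beta = natural_from_alpha(alpha)
        sd = sigma0 / np.sqrt(2.0 * beta)
        return mu - 12.0 * sd, mu + 12.0 * sd, mu

    def default_grid(alpha, n):
        mu, beta = natural_from_alpha(alpha)
        sd = sigma0 / np.sqrt(2.0 * beta)
        return np.linspace(mu - 10.0 * sd, mu + 10.0 * sd, n)

    def matrices(alpha):
        mu, beta = natural_from_alpha(alpha)
        return ou_matrices(mu, beta, sigma0)

    return ModelSpec(
        name="ou",
        dim=2,
        domain=(-np.inf, np.inf),
        observables=observables,
        observable_grad=observable_grad,
        observable_lap=observable_lap,
        noise_g2=lambda x: np.full_like(np.asarray(x, float), s2),
        noise_g2_prime=lambda x: np.zeros_like(np.asarray(x, float)),
        log_baseline=lambda x: np.zeros_like(np.asarray(x, float)),
        force_scale=1.0 / s2,
        validity=validity,
        quad_bounds=quad_bounds,
        default_grid=default_grid,
        matrices=matrices,
        to_unconstrained=lambda a: np.array([a[0], np.log(-a[1])]),
        from_unconstrained=lambda z: np.array([z[0], -np.exp(z[1])]),
    )


# --------------------------------------------------------------------------
# exact Gaussian dynamics
# --------------------------------------------------------------------------

def ou_closed_form_moments(mu0, beta0, mu_inf, beta_inf, sigma0, times):
    """Constant-coefficient solution m(t), v(t) from a stationary start."""
    t = np.asarray(times, dtype=float)
    m = mu_inf + (mu0 - mu_inf) * np.exp(-beta_inf * t)
    v0 = sigma0**2 / (2.0 * beta0)
    v_inf = sigma0**2 / (2.0 * beta_inf)
    v = v0 * np.exp(-2.0 * beta_inf * t) + v_inf * (1.0 - np.exp(-2.0 * beta_inf * t))
    return m, v


def ou_exact_moments(params: OUParams, times, method: str = "auto",
                     rtol: float = 1e-10, atol: float = 1e-12):
    """Exact mean/variance path of the OU process.

    For protocols that are constant after t=0 (constant or a single step at
    t=0) the explicit exponential solution is used; otherwise the moment ODEs
    dm/dt = beta(t)(mu(t) - m), dv/dt = sigma0^2 - 2 beta(t) v are integrated.
    These moment equations are the (m, v) form of the Gaussian f/g/h system;
    both routes agree wherever both apply.  Returns a list of
    :class:`GaussianState`.
    """
    times = np.asarray(times, dtype=float)
    proto = params.protocol
    constant_after_0 = proto.kind == "constant" or (
        proto.kind == "step" and proto.switch_times == (0.0,) and times[0] >= 0.0)
    if method == "closed" or (method == "auto" and constant_after_0):
        if not constant_after_0:
            raise ValueError("closed form requires coefficients constant for t>=0")
        mu_inf, beta_inf = proto(max(times[0], 0.0) + 1e-12)
        if beta_inf <= 0:
            raise ValidityError("beta must stay positive")
        m, v = ou_closed_form_moments(params.mu0, params.beta0, mu_inf,
                                      beta_inf, params.sigma0, times)
        return [GaussianState(mi, vi) for mi, vi in zip(m, v)]

    def rhs(t, y):
        mu_t, beta_t = proto(t)
        if beta_t <= 0:
            raise ValidityError(f"beta(t) must be positive (t={t})")
        return [beta_t * (mu_t - y[0]), params.sigma0**2 - 2.0 * beta_t * y[1]]

    y = np.array([params.mu0, params.sigma0**2 / (2.0 * params.beta0)])
    out = [GaussianState(*y)]
    edges = [times[0]] + proto.switches_in(times[0], times[-1]) + [times[-1]]
    state = y.copy()
    idx = 1
    for t0, t1 in zip(edges[:-1], edges[1:]):
        if t1 <= t0:
            continue
        sol = integrate.solve_ivp(rhs, (t0, t1), state, method="LSODA",
                                  dense_output=True, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(sol.message)
        for te in times[(times > t0) & (times <= t1)]:
            out.append(GaussianState(*sol.sol(te)))
            idx += 1
        state = sol.y[:, -1]
    return out


# --------------------------------------------------------------------------
# DME dynamics (exact for the OU process)
# --------------------------------------------------------------------------

def ou_dme_rhs(mu_star, beta_star, mu_t, beta_t):
    """Decoupled effective-force derivatives (independent of sigma0)."""
    if beta_star <= 0:
        raise ValidityError("beta* must be positive")
    return beta_t * (mu_t - mu_star), 2.0 * beta_star * (beta_t - beta_star)


def ou_dme_solution(params: OUParams, times, rtol: float = 1e-8,
                    atol: float = 1e-10):
    """Integrate the effective-force system and map to Gaussian moments.

    Returns (mu_star, beta_star, states) where states are GaussianState with
    m = mu*, v = sigma0^2/(2 beta*).
    """
    times = np.asarray(times, dtype=float)
    proto = params.protocol

    def rhs(t, y):
        mu_t, beta_t = proto(t)
        return ou_dme_rhs(y[0], y[1], mu_t, beta_t)

    state = np.array([params.mu0, params.beta0])
    mu_s = np.empty(len(times))
    beta_s = np.empty(len(times))
    mu_s[0], beta_s[0] = state
    edges = [times[0]] + proto.switches_in(times[0], times[-1]) + [times[-1]]
    idx = 1
    for t0, t1 in zip(edges[:-1], edges[1:]):
        if t1 <= t0:
            continue
        sol = integrate.solve_ivp(rhs, (t0, t1), state, method="LSODA",
                                  dense_output=True, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(sol.message)
        for te in times[(times > t0) & (times <= t1)]:
            mu_s[idx], beta_s[idx] = sol.sol(te)
            idx += 1
        state = sol.y[:, -1]
    states = [GaussianState(m, params.sigma0**2 / (2.0 * b))
              for m, b in zip(mu_s, beta_s)]
    return mu_s, beta_s, states
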