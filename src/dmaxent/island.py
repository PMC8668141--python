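"""Stochastic logistic island model with immigration.

The population size n(t) on a single island follows

    dn = [n(r - lambda n) + m] dt + sqrt(n) dxi,

with intrinsic growth rate r [1/time], density regulation lambda = r/K
[1/(time * individuals)], immigration rate m [individuals/time] and
demographic variance scale fixed at gamma = 1 (Poisson(1) offspring number).
The stationary density is (1/Z) n^{2m-1} exp(-lambda n^2 + 2 r n): an
exponential family with baseline 1/n, observables A = (n, -n^2/2, log n),
forces alpha = (r, lambda, m) and exponent scale s = 2.

All stationary moments reduce to the integrals

    G(k)    = int_0^inf n^{k+2m-1} exp(-lambda n^2 + 2 r n) dn,
    H(k, j) = int_0^inf n^{k+2m-1} (log n)^j exp(-lambda n^2 + 2 r n) dn,

with G(k) finite iff k + 2m > 0.  G has a closed form in confluent
hypergeometric (Kummer) functions which serves as a cross-check; adaptive
quadrature is the production route.  The DME reduction is valid only for
m > 1/2: below that threshold <1/n>, which enters the matrix B, diverges
because the ansatz behaves like n^{2m-1} near n = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, special

from .core import DomainError, ModelSpec, MomentMatrices, ValidityError

__all__ = [
    "IslandForces",
    "ValidityReport",
    "G",
    "H",
    "stationary_mode",
    "island_moments",
    "island_matrices",
    "island_moment_rhs",
    "island_model",
    "check_dme_validity",
    "estimate_validity_threshold",
]


# --------------------------------------------------------------------------
# forces
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IslandForces:
    """Ecological force triple (r, lambda, m); gamma is fixed at 1."""

    r: float
    lam: float
    m: float

    @property
    def carrying_capacity(self) -> float:
        return self.r / self.lam

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.lam, self.m])


def _unpack(forces):
    if isinstance(forces, IslandForces):
        return forces.r, forces.lam, forces.m
    r, lam, m = np.asarray(forces, dtype=float)
    return float(r), float(lam), float(m)


@dataclass(frozen=True)
class ValidityReport:
    valid: bool
    violations: tuple = ()

    def __bool__(self):
        return self.valid


def check_dme_validity(forces) -> ValidityReport:
    """DME validity: lambda > 0 and m > 1/2 (strict).

    At m = 1/2 the stationary ansatz behaves like a constant near n = 0 and
    <1/n>, which enters the matrix B, is log-divergent; for m < 1/2 it
    diverges as a power.  A boundary-layer treatment of the m < 1/2 regime
    exists in the quantitative-genetics literature but is out of scope here.
    """
    r, lam, m = _unpack(forces)
    violations = []
    if not np.isfinite([r, lam, m]).all():
        violations.append("non-finite force entries")
    if lam <= 0:
        violations.append(f"lambda = {lam} must be positive (integrable tail)")
    if m <= 0.5:
        violations.append(
            f"m = {m} <= 1/2: <1/n> in the matrix B diverges "
            "(a boundary-layer correction would be needed; not implemented)")
    return ValidityReport(valid=not violations, violations=tuple(violations))


# --------------------------------------------------------------------------
# G(k) and H(k, j)
# --------------------------------------------------------------------------

def _log_integrand_max(nu, r, lam):
    """Argmax and max of nu*u + 2 r e^u - lambda e^{2u} over u = log n.

    This is the log of the integrand of G in u-coordinates, where the measure
    n^{nu-1} dn becomes exactly e^{nu u} du.
    """
    n_star = (r + math.sqrt(r * r + 2.0 * lam * nu)) / (2.0 * lam)
    u_star = math.log(n_star)
    val = nu * u_star + 2.0 * r * n_star - lam * n_star * n_star
    return val, u_star


def G(k: float, forces, method: str = "quad") -> float:
    """Unnormalized moment integral G(k) = int n^{k+2m-1} e^{-lam n^2 + 2 r n}.

    ``method='quad'`` (production) uses adaptive quadrature; ``'kummer'``
    evaluates the closed form in Kummer functions, in 50-digit arithmetic when
    mpmath is importable and in double precision otherwise.
    """
    r, lam, m = _unpack(forces)
    if lam <= 0:
        raise DomainError(f"lambda = {lam} must be positive")
    nu = k + 2.0 * m
    if nu <= 0:
        raise DomainError(
            f"G({k}) diverges: requires k + 2m > 0, got {nu:.4g} "
            "(convergence condition of the moment integral)")
    if method == "kummer":
        return _G_kummer(nu, r, lam)
    if method != "quad":
        raise ValueError(f"unknown method {method!r}")
    peak, val = _weighted_quad(nu, r, lam)
    return math.exp(peak) * val


def _weighted_quad(nu, r, lam, j: int = 0):
    """(peak, value) with int n^{nu-1} (log n)^j e^{2rn - lam n^2} dn equal to
    e^peak * value, by adaptive quadrature in u = log n split at the peak."""
    peak, u_star = _log_integrand_max(nu, r, lam)
    width = 1.0 / math.sqrt(nu + 2.0 * lam * math.exp(2.0 * u_star))

    def f(u):
        w = np.exp(nu * u + 2.0 * r * np.exp(u) - lam * np.exp(2.0 * u) - peak)
        return w * u**j if j else w

    opts = dict(limit=400, epsabs=1e-14, epsrel=1e-11)
    core, _ = integrate.quad(f, u_star - 30.0 * width, u_star + 30.0 * width,
                             points=[u_star, 0.0]
                             if abs(u_star) < 30.0 * width else [u_star],
                             **opts)
    lo_tail, _ = integrate.quad(f, -np.inf, u_star - 30.0 * width, limit=200)
    hi_tail, _ = integrate.quad(f, u_star + 30.0 * width, np.inf, limit=200)
    return peak, core + lo_tail + hi_tail


def _G_kummer(nu, r, lam):
    z = r * r / lam
    try:
        import mpmath as mp
        with mp.workdps(50):
            t1 = mp.mpf(0.5) * mp.power(lam, -nu / 2) * mp.gamma(nu / 2) \
                * mp.hyp1f1(nu / 2, mp.mpf(0.5), z)
            t2 = mp.mpf(r) * mp.power(lam, -(nu + 1) / 2) \
                * mp.gamma((nu + 1) / 2) * mp.hyp1f1((nu + 1) / 2, mp.mpf(1.5), z)
            return float(t1 + t2)
    except ImportError:
        t1 = 0.5 * lam ** (-nu / 2) * special.gamma(nu / 2) \
            * special.hyp1f1(nu / 2, 0.5, z)
        t2 = r * lam ** (-(nu + 1) / 2) * special.gamma((nu + 1) / 2) \
            * special.hyp1f1((nu + 1) / 2, 1.5, z)
        return t1 + t2


def H(k: float, j: int, forces, method: str = "quad",
      fd_step: float = 1e-4) -> float:
    """Unnormalized log-weighted integral int n^{k+2m-1} (log n)^j e^{...} dn.

    ``method='quad'`` (production) integrates the log weight directly;
    ``'fd'`` uses the identity H(k, j) = (1/2^j) d^j G(k)/dm^j with central
    finite differences — the analytic route, kept as a cross-check
    because high-order m-differentiation of the Kummer form is
    ill-conditioned.
    """
    r, lam, m = _unpack(forces)
    if j < 0 or j > 2 or int(j) != j:
        raise ValueError("j must be 0, 1 or 2")
    j = int(j)
    if j == 0:
        return G(k, (r, lam, m), method="quad" if method != "kummer" else method)
    nu = k + 2.0 * m
    if nu <= 0:
        raise DomainError(f"H({k},{j}) diverges: requires k + 2m > 0")
    if method == "fd":
        h = fd_step
        if j == 1:
            d = (G(k, (r, lam, m + h)) - G(k, (r, lam, m - h))) / (2.0 * h)
        else:
            d = (G(k, (r, lam, m + h)) - 2.0 * G(k, (r, lam, m))
                 + G(k, (r, lam, m - h))) / h**2
        return d / 2.0**j
    if method != "quad":
        raise ValueError(f"unknown method {method!r}")
    peak, val = _weighted_quad(nu, r, lam, j=j)
    return math.exp(peak) * val


def stationary_mode(forces) -> float:
    """Mode of the stationary density: root of d/dn log u = 0."""
    r, lam, m = _unpack(forces)
    disc = r * r + 2.0 * lam * (2.0 * m - 1.0)
    if disc < 0:
        raise DomainError("stationary density has no interior mode")
    return (r + math.sqrt(disc)) / (2.0 * lam)


# --------------------------------------------------------------------------
# fast vectorized moment bundle (memoized per force point)
# --------------------------------------------------------------------------

_REQUIRED = [(-1, 0), (0, 0), (1, 0), (2, 0), (3, 0), (4, 0),
             (0, 1), (1, 1), (2, 1), (0, 2)]

_BUNDLE_CACHE: dict = {}


@dataclass
class IslandMomentSet:
    """Normalized stationary moments at one force point."""

    forces: tuple
    n: float
    n2: float
    n3: float
    n4: float
    inv_n: float
    log_n: float
    n_log_n: float
    n2_log_n: float
    log_n_sq: float
    log_Z: float = field(default=np.nan)

    def as_dict(self):
        return {"n": self.n, "n2": self.n2, "n3": self.n3, "n4": self.n4,
                "inv_n": self.inv_n, "log_n": self.log_n,
                "n_log_n": self.n_log_n, "n2_log_n": self.n2_log_n,
                "log_n_sq": self.log_n_sq}

    @property
    def observable_means(self) -> np.ndarray:
        """<A> for A = (n, -n^2/2, log n)."""
        return np.array([self.n, -0.5 * self.n2, self.log_n])


def island_moments(forces, n_points: int = 6000) -> IslandMomentSet:
    """All stationary moments needed by the DME matrices, in one pass.

    Integrates in u = log n on a composite grid (uniform in u through the
    lower tail, uniform in n across the peak) with Simpson's rule; the
    analytically known power-law lower tail below the grid is added in closed
    form.  Results are memoized per force point since the ODE right-hand side
    revisits nearby points constantly.
    """
    r, lam, m = _unpack(forces)
    key = (round(r, 13), round(lam, 13), round(m, 13), n_points)
    hit = _BUNDLE_CACHE.get(key)
    if hit is not None:
        return hit
    rep = check_dme_validity((r, lam, m))
    if not rep:
        raise ValidityError("; ".join(rep.violations))

    sigma = 1.0 / math.sqrt(2.0 * lam)
    mode4 = (r + math.sqrt(r * r + 2.0 * lam * (4.0 + 2.0 * m))) / (2.0 * lam)
    n_max = mode4 + 18.0 * sigma
    # composite grid in u = log n: log-uniform through the power-law lower
    # tail (step du), switching to n-uniform where that becomes the finer of
    # the two; below u_cut = -40 the exponential factors are 1 to double
    # precision and the pure-power tail is added analytically
    u_cut = -40.0
    du = 0.02
    dn = n_max / n_points
    junction = min(max(dn / du, math.exp(u_cut + 1.0)), 0.5 * n_max)
    n_tail = max(int((math.log(junction) - u_cut) / du), 50)
    u_tail = np.linspace(u_cut, math.log(junction), n_tail)
    u_peak = np.log(np.linspace(junction, n_max, n_points))
    u = np.unique(np.concatenate([u_tail, u_peak]))
    n = np.exp(u)
    base = 2.0 * r * n - lam * n * n  # exponent minus the power-law part

    scaled = {}
    logM = {}
    for k, j in _REQUIRED:
        nu = k + 2.0 * m
        L = nu * u + base
        Mkj = float(np.max(L))
        w = np.exp(L - Mkj)
        if j:
            w = w * u**j
        val = float(integrate.simpson(w, x=u))
        # analytic pure-power tail below u_cut: int_{-inf}^{u_cut} u^j e^{nu u} du
        e = math.exp(nu * u_cut - Mkj)
        if j == 0:
            val += e / nu
        elif j == 1:
            val += e * (u_cut / nu - 1.0 / nu**2)
        else:
            val += e * (u_cut**2 / nu - 2.0 * u_cut / nu**2 + 2.0 / nu**3)
        scaled[(k, j)] = val
        logM[(k, j)] = Mkj

    def ratio(k, j):
        return scaled[(k, j)] / scaled[(0, 0)] * math.exp(logM[(k, j)] - logM[(0, 0)])

    out = IslandMomentSet(
        forces=(r, lam, m),
        n=ratio(1, 0), n2=ratio(2, 0), n3=ratio(3, 0), n4=ratio(4, 0),
        inv_n=ratio(-1, 0), log_n=ratio(0, 1), n_log_n=ratio(1, 1),
        n2_log_n=ratio(2, 1), log_n_sq=ratio(0, 2),
        log_Z=logM[(0, 0)] + math.log(scaled[(0, 0)]),
    )
    if len(_BUNDLE_CACHE) > 8192:
        _BUNDLE_CACHE.clear()
    _BUNDLE_CACHE[key] = out
    return out


# --------------------------------------------------------------------------
# DME ingredients
# --------------------------------------------------------------------------

def island_matrices(forces, scale_covariance: bool = True) -> MomentMatrices:
    """B, V, Cov and the sensitivity C at an effective force point.

    ``scale_covariance=True`` (default) uses the chain-rule-consistent
    C = 2 Cov(A) = d<A>/d(alpha), since the exponent of the stationary density
    is 2 alpha . A; ``False`` uses the plain covariance instead.
    """
    r, lam, m = _unpack(forces)
    mom = island_moments((r, lam, m))
    B = np.array([
        [mom.n, -mom.n2, 1.0],
        [-mom.n2, mom.n3, -mom.n],
        [1.0, -mom.n, mom.inv_n],
    ])
    V = np.array([0.0, -mom.n, -mom.inv_n])
    c11 = mom.n2 - mom.n**2
    c12 = -0.5 * (mom.n3 - mom.n * mom.n2)
    c13 = mom.n_log_n - mom.n * mom.log_n
    c22 = 0.25 * (mom.n4 - mom.n2**2)
    c23 = -0.5 * (mom.n2_log_n - mom.n2 * mom.log_n)
    c33 = mom.log_n_sq - mom.log_n**2
    Cov = np.array([[c11, c12, c13], [c12, c22, c23], [c13, c23, c33]])
    C = 2.0 * Cov if scale_covariance else Cov.copy()
    return MomentMatrices(B=B, V=V, Cov=Cov, C=C)


def island_moment_rhs(moments, applied) -> np.ndarray:
    """Explicit moment ODE right-hand side for A = (n, -n^2/2, log n).

    ``moments`` may be an :class:`IslandMomentSet` or a mapping with keys
    'n', 'n2', 'n3', 'inv_n'.  Identical to the B alpha + V/2 assembly.
    """
    r, lam, m = _unpack(applied)
    if isinstance(moments, IslandMomentSet):
        En, En2, En3, Einv = moments.n, moments.n2, moments.n3, moments.inv_n
    else:
        En, En2, En3, Einv = (moments["n"], moments["n2"],
                              moments["n3"], moments["inv_n"])
    return np.array([
        r * En - lam * En2 + m,
        -(m + 0.5) * En - r * En2 + lam * En3,
        r - lam * En + (m - 0.5) * Einv,
    ])


# --------------------------------------------------------------------------
# ModelSpec for the generic engine
# --------------------------------------------------------------------------

def island_model(scale_covariance: bool = True) -> ModelSpec:
    """Generic-engine specification of the island model."""

    def observables(x):
        return np.stack([x, -0.5 * x * x, np.log(x)])

    def observable_grad(x):
        return np.stack([np.ones_like(x), -x, 1.0 / x])

    def observable_lap(x):
        return np.stack([np.zeros_like(x), -np.ones_like(x), -1.0 / x**2])

    def validity(alpha):
        return list(check_dme_validity(alpha).violations)

    def quad_bounds(alpha):
        r, lam, m = _unpack(alpha)
        mode = stationary_mode(alpha)
        sigma = 1.0 / math.sqrt(2.0 * lam)
        lo = mode * 1e-12
        hi = mode + 18.0 * sigma
        return lo, hi, mode

    def default_grid(alpha, n):
        r, lam, m = _unpack(alpha)
        mode = stationary_mode(alpha)
        sigma = 1.0 / math.sqrt(2.0 * lam)
        n_max = mode + 15.0 * sigma
        # choose the left edge so the analytic mass below it is < 1e-10:
        # near 0 the unnormalized density is ~ n^{2m-1}, so the cumulative
        # below eps is eps^{2m}/(2m); compare against the peak contribution
        probe = np.geomspace(mode * 1e-9, n_max, 2001)
        logu = (2.0 * m - 1.0) * np.log(probe) + 2.0 * r * probe - lam * probe**2
        vals = np.exp(logu - logu.max())
        cum = integrate.cumulative_trapezoid(vals, probe, initial=0.0)
        cum /= cum[-1]
        i_lo = int(np.searchsorted(cum, 1e-10))
        n_lo = probe[max(i_lo, 1) - 1]
        n_split = max(mode / 3.0, 2.0 * n_lo)
        k = max(n // 4, 50)
        left = np.geomspace(n_lo, n_split, k, endpoint=False)
        right = np.linspace(n_split, n_max, n - k)
        return np.concatenate([left, right])

    def matrices(alpha):
        return island_matrices(alpha, scale_covariance=scale_covariance)

    return ModelSpec(
        name="island",
        dim=3,
        domain=(0.0, np.inf),
        observables=observables,
        observable_grad=observable_grad,
        observable_lap=observable_lap,
        noise_g2=lambda x: np.asarray(x, dtype=float),
        noise_g2_prime=lambda x: np.ones_like(np.asarray(x, float)),
        log_baseline=lambda x: -np.log(x),
        force_scale=2.0,
        validity=validity,
        quad_bounds=quad_bounds,
        default_grid=default_grid,
        matrices=matrices,
        to_unconstrained=lambda a: np.array(
            [a[0], np.log(a[1]), np.log(a[2] - 0.5)]),
        from_unconstrained=lambda z: np.array(
            [z[0], np.exp(z[1]), 0.5 + np.exp(z[2])]),
    )


# --------------------------------------------------------------------------
# the m = 1/2 validity frontier
# --------------------------------------------------------------------------

def _inv_n_integrable(m: float, r: float = 0.1, lam: float = 0.002) -> bool:
    """Numerical integrability probe for <1/n> at migration rate m.

    Compares successive lower-cutoff increments of int_eps^1 n^{2m-2} e^{...}:
    shrinking increments mean convergence (m > 1/2), growing ones divergence.
    """
    cuts = (1e-4, 1e-6, 1e-8)
    vals = []
    for eps in cuts:
        # u = log n removes the endpoint singularity from the quadrature
        v, _ = integrate.quad(
            lambda u: np.exp((2.0 * m - 1.0) * u + 2.0 * r * np.exp(u)
                             - lam * np.exp(2.0 * u)),
            np.log(eps), 0.0, limit=200)
        vals.append(v)
    inc1 = vals[1] - vals[0]
    inc2 = vals[2] - vals[1]
    if inc1 <= 0:
        return True
    return inc2 / inc1 < 1.0


def estimate_validity_threshold(tol: float = 1e-4, lo: float = 0.3,
                                hi: float = 0.8) -> float:
    """Bisection on the integrability of <1/n>: localizes the m = 1/2 frontier."""
    if _inv_n_integrable(lo) or not _inv_n_integrable(hi):
        raise RuntimeError("bracket does not straddle the integrability frontier")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _inv_n_integrable(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
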