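"""Numerical reference solutions for the validation stack.

Two independent references for the same stochastic dynamics:

* a conservative finite-volume Fokker-Planck solver with a Chang-Cooper
  (exponentially fitted) flux discretization and discrete no-flux boundaries,
  integrated in time by a stiff BDF method;
* for the island model, a continuous-time birth-death chain on the
  nonnegative integers whose drift matches the SDE exactly (the jump-rate
  split is one admissible choice; the chain's variance m + n + lambda n^2
  only approximates the diffusion's n, a known discrepancy of the discrete
  analogue).

The Chang-Cooper weights make the discrete stationary state satisfy
u_{i+1}/u_i = exp(a_f dx / D_f) across every face, so the scheme's fixed
point matches the analytic stationary density to second order in dx and the
numerical flux vanishes identically there (discrete detailed balance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, sparse

from .core import DomainError, GriddedDensity, ModelSpec, stationary_density
from .protocols import DriveProtocol

__all__ = [
    "FPEGrid",
    "make_grid",
    "scheme_stationary",
    "solve_fpe",
    "BirthDeathChain",
    "build_birth_death",
    "solve_master",
]


# --------------------------------------------------------------------------
# grid
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FPEGrid:
    """Uniform cell-centered grid on [lo, hi]."""

    lo: float
    hi: float
    n_cells: int

    @property
    def dx(self) -> float:
        return (self.hi - self.lo) / self.n_cells

    @property
    def centers(self) -> np.ndarray:
        return self.lo + (np.arange(self.n_cells) + 0.5) * self.dx

    @property
    def interior_faces(self) -> np.ndarray:
        return self.lo + np.arange(1, self.n_cells) * self.dx


def make_grid(model: ModelSpec, alphas, n_cells: int = 400) -> FPEGrid:
    """Grid wide enough that every listed force level keeps its stationary
    mass outside below ~1e-10."""
    los, his = [], []
    for a in alphas:
        g = model.default_grid(np.asarray(a, float), 512)
        los.append(g[0])
        his.append(g[-1])
    return FPEGrid(lo=min(los), hi=max(his), n_cells=n_cells)


# --------------------------------------------------------------------------
# Chang-Cooper operator
# --------------------------------------------------------------------------

def _face_data(model: ModelSpec, grid: FPEGrid):
    xf = grid.interior_faces
    D = 0.5 * model.noise_g2(xf)
    Dp = 0.5 * model.noise_g2_prime(xf)
    # drift of the *flux form* J = (a - D') u - D u' with a the SDE drift
    P = 0.5 * model.noise_g2(xf) * model.force_scale * model.observable_grad(xf)
    return xf, D, Dp, P  # P rows: per-force contribution to the SDE drift


def _cc_weights(w):
    """Right-cell weight 1/w - 1/(e^w - 1), series-expanded near w = 0."""
    w = np.asarray(w, dtype=float)
    out = np.empty_like(w)
    small = np.abs(w) < 1e-6
    ws = w[~small]
    out[~small] = 1.0 / ws - 1.0 / np.expm1(ws)
    out[small] = 0.5 - w[small] / 12.0
    return out


def _assemble(model: ModelSpec, grid: FPEGrid, alpha, face_data=None):
    """Tridiagonal L with du/dt = L u and zero-flux boundaries."""
    if face_data is None:
        face_data = _face_data(model, grid)
    xf, D, Dp, P = face_data
    h = grid.dx
    a_tilde = np.asarray(alpha, float) @ P - Dp
    w = a_tilde * h / D
    wr = _cc_weights(w)
    # flux at face f (between cells f-1 and f):
    #   J_f = a~ [(1-wr) uL + wr uR] - (D/h)(uR - uL)
    cL = a_tilde * (1.0 - wr) + D / h   # coefficient of u_{f-1} in J_f
    cR = a_tilde * wr - D / h           # coefficient of u_f in J_f
    n = grid.n_cells
    main = np.zeros(n)
    lower = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    # du_i/dt = (J_i - J_{i+1}) / h, boundary fluxes J_0 = J_n = 0
    main[:-1] -= cL / h   # -J_{i+1} contribution to cell i
    upper[:] -= cR / h
    main[1:] += cR / h    # +J_i contribution to cell i
    lower[:] += cL / h
    return sparse.diags_array([lower, main, upper], offsets=(-1, 0, 1),
                              format="csr")


def scheme_stationary(model: ModelSpec, grid: FPEGrid, alpha) -> GriddedDensity:
    """Exact stationary state of the discrete scheme (zero flux at all faces)."""
    xf, D, Dp, P = _face_data(model, grid)
    a_tilde = np.asarray(alpha, float) @ P - Dp
    w = a_tilde * grid.dx / D
    logu = np.concatenate([[0.0], np.cumsum(w)])
    logu -= logu.max()
    u = np.exp(logu)
    u /= u.sum() * grid.dx
    return GriddedDensity(grid.centers, u)


def solve_fpe(model: ModelSpec, protocol: DriveProtocol,
              initial: GriddedDensity, times, grid: FPEGrid | None = None,
              n_cells: int = 400, rtol: float = 1e-8, atol: float = 1e-13,
              mass_tol: float = 1e-6) -> list[GriddedDensity]:
    """Method-of-lines solution of the 1D FPE along a drive protocol.

    The operator is reassembled per protocol segment (piecewise-constant
    drives) or per evaluation (continuous drives); BDF time stepping restarts
    at every declared switch time.  Mass conservation is monitored at every
    output time and drift beyond ``mass_tol`` aborts the run.
    """
    times = np.asarray(times, dtype=float)
    if grid is None:
        levels = protocol.levels if protocol.levels else (protocol(times[0]),)
        grid = make_grid(model, levels, n_cells)
    u0 = initial.interp_to(grid.centers).values.copy()
    u0 /= u0.sum() * grid.dx
    face_data = _face_data(model, grid)

    out: list[GriddedDensity | None] = [None] * len(times)
    out[0] = GriddedDensity(grid.centers, np.clip(u0, 0.0, None))
    piecewise_const = protocol.kind in ("constant", "step", "square_wave")

    edges = [times[0]] + protocol.switches_in(times[0], times[-1]) + [times[-1]]
    state = u0
    idx = 1
    for t0, t1 in zip(edges[:-1], edges[1:]):
        if t1 <= t0:
            continue
        if piecewise_const:
            L = _assemble(model, grid, protocol(0.5 * (t0 + t1)), face_data)

            def rhs(t, u, L=L):
                return L @ u

            def jac(t, u, L=L):
                return L
        else:
            def rhs(t, u):
                return _assemble(model, grid, protocol(t), face_data) @ u

            def jac(t, u):
                return _assemble(model, grid, protocol(t), face_data)

        eval_t = times[(times > t0) & (times <= t1)]
        sol = integrate.solve_ivp(rhs, (t0, t1), state, method="BDF",
                                  t_eval=eval_t if len(eval_t) else None,
                                  jac=jac, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"FPE integration failed on [{t0}, {t1}]: "
                               + sol.message)
        for k in range(sol.y.shape[1] if len(eval_t) else 0):
            u = sol.y[:, k]
            mass = u.sum() * grid.dx
            if abs(mass - 1.0) > mass_tol:
                raise RuntimeError(
                    f"FPE mass drifted to {mass:.10f} at t={eval_t[k]:.4g}")
            if u.min() < -1e-9:
                raise RuntimeError(
                    f"FPE produced negative density {u.min():.3e} "
                    f"at t={eval_t[k]:.4g}")
            out[idx] = GriddedDensity(grid.centers, np.clip(u, 0.0, None))
            idx += 1
        # continue from the segment end state
        if len(eval_t) and eval_t[-1] == t1:
            state = sol.y[:, -1]
        else:
            tail = integrate.solve_ivp(rhs, (eval_t[-1] if len(eval_t) else t0, t1),
                                       sol.y[:, -1] if len(eval_t) else state,
                                       method="BDF", jac=jac, rtol=rtol, atol=atol)
            state = tail.y[:, -1]
    return out


# --------------------------------------------------------------------------
# birth-death chain
# --------------------------------------------------------------------------

@dataclass
class BirthDeathChain:
    """Continuous-time birth-death process on {0, ..., N_max}.

    Rates are the drift-matching split b_n = m + n(1+r)/2,
    d_n = n(1-r)/2 + lambda n^2, so b_n - d_n = n(r - lambda n) + m equals the
    SDE drift exactly while the jump variance b_n + d_n = m + n + lambda n^2
    approximates the diffusion's n.
    """

    N_max: int
    b: np.ndarray
    d: np.ndarray

    @property
    def generator(self) -> sparse.csr_array:
        b, d = self.b, self.d
        main = -(b + d)
        return sparse.diags_array([d[1:], main, b[:-1]], offsets=(-1, 0, 1),
                                  format="csr")

    def stationary(self) -> np.ndarray:
        """Stationary pmf via detailed balance pi_n b_n = pi_{n+1} d_{n+1},
        accumulated in log space."""
        with np.errstate(divide="ignore"):
            steps = np.log(self.b[:-1]) - np.log(self.d[1:])
        logpi = np.concatenate([[0.0], np.cumsum(steps)])
        logpi -= logpi.max()
        pi = np.exp(logpi)
        return pi / pi.sum()


def build_birth_death(forces, N_max: int) -> BirthDeathChain:
    from .island import _unpack
    r, lam, m = _unpack(forces)
    if abs(r) > 1:
        raise ValueError(
            f"|r| = {abs(r)} > 1: the rate split b_n = m + n(1+r)/2, "
            "d_n = n(1-r)/2 + lambda n^2 needs nonnegative rates")
    n = np.arange(N_max + 1, dtype=float)
    b = m + n * (1.0 + r) / 2.0
    d = n * (1.0 - r) / 2.0 + lam * n * n
    b[-1] = 0.0  # truncation: no births out of the top state
    return BirthDeathChain(N_max=N_max, b=b, d=d)


def solve_master(chain_or_protocol, p0, times, N_max: int | None = None,
                 rtol: float = 1e-8, atol: float = 1e-13,
                 tail_tol: float = 1e-6) -> np.ndarray:
    """Integrate the master equation dp/dt = Q^T p.

    Accepts either a fixed :class:`BirthDeathChain` or a
    :class:`DriveProtocol` of island forces together with ``N_max`` (the
    generator is rebuilt at every protocol switch).  Returns an array of
    shape (len(times), N_max+1).  Tail mass at the truncation boundary above
    ``tail_tol`` raises with advice to enlarge N_max.
    """
    times = np.asarray(times, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    if isinstance(chain_or_protocol, BirthDeathChain):
        protocol = DriveProtocol.constant([0.0])  # dummy, single segment
        builder = lambda t: chain_or_protocol
        switches = []
    else:
        protocol = chain_or_protocol
        if N_max is None:
            raise ValueError("N_max required when passing a protocol")
        builder = lambda t: build_birth_death(protocol(t), N_max)
        switches = protocol.switches_in(times[0], times[-1])

    out = np.empty((len(times), len(p0)))
    out[0] = p0
    state = p0.copy()
    edges = [times[0]] + switches + [times[-1]]
    idx = 1
    for t0, t1 in zip(edges[:-1], edges[1:]):
        if t1 <= t0:
            continue
        QT = builder(0.5 * (t0 + t1)).generator.T.tocsr()
        sol = integrate.solve_ivp(lambda t, p: QT @ p, (t0, t1), state,
                                  method="BDF", jac=lambda t, p: QT,
                                  t_eval=times[(times > t0) & (times <= t1)]
                                  if np.any((times > t0) & (times <= t1)) else None,
                                  rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(sol.message)
        eval_t = times[(times > t0) & (times <= t1)]
        for k in range(sol.y.shape[1] if len(eval_t) else 0):
            p = sol.y[:, k]
            if p[-1] > tail_tol:
                raise DomainError(
                    f"pmf tail mass {p[-1]:.2e} at N_max: increase N_max")
            out[idx] = p
            idx += 1
        if len(eval_t) and eval_t[-1] == t1:
            state = sol.y[:, -1]
        else:
            tail = integrate.solve_ivp(lambda t, p: QT @ p,
                                       (eval_t[-1] if len(eval_t) else t0, t1),
                                       sol.y[:, -1] if len(eval_t) else state,
                                       method="BDF", jac=lambda t, p: QT,
                                       rtol=rtol, atol=atol)
            state = tail.y[:, -1]
    return out
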