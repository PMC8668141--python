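"""Seeded Euler-Maruyama ensembles and stationary-distribution sampling.

The Monte-Carlo ground truth: ensembles of SDE sample paths for the OU and
island models, initialized from the stationary distribution of the starting
forces and advanced with a fixed-step Euler-Maruyama scheme.  Randomness is
organized as one child seed-sequence stream per trajectory, so results are
bit-reproducible for a given (seed, dt, n_traj, protocol) and individual
trajectories do not change when more are appended.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ModelSpec, stationary_density
from .protocols import DriveProtocol

__all__ = [
    "TrajectoryEnsemble",
    "simulate_ou",
    "simulate_island",
    "sample_stationary",
    "ensemble_moments",
]

_CHUNK = 512  # trajectories advanced together (bounds the noise buffer)


@dataclass
class TrajectoryEnsemble:
    """SDE sample paths recorded on a shared time grid."""

    times: np.ndarray            # (n_times,)
    paths: np.ndarray            # (n_traj, n_times)
    dt: float
    seed: int
    model: str
    protocol: DriveProtocol | None = None

    @property
    def n_traj(self) -> int:
        return self.paths.shape[0]


def _record_grid(t_end, dt, record_every):
    n_steps = int(round(t_end / dt))
    rec = np.arange(0, n_steps + 1, record_every)
    if rec[-1] != n_steps:
        rec = np.append(rec, n_steps)
    return n_steps, rec


def sample_stationary(model: ModelSpec, alpha, n_samples: int,
                      seed_or_rng, n_grid: int = 4001) -> np.ndarray:
    """Inverse-CDF samples from the stationary density at the given forces."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    dens = stationary_density(model, alpha, n_points=n_grid)
    cdf = np.concatenate([[0.0], np.cumsum(
        0.5 * (dens.values[1:] + dens.values[:-1]) * np.diff(dens.grid))])
    cdf /= cdf[-1]
    u = rng.random(n_samples)
    return np.interp(u, cdf, dens.grid)


def _spawn_rngs(seed, n):
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(n)]


def simulate_ou(params, n_traj: int, dt: float, seed: int, t_end: float,
                record_every: int = 10, noise_off: bool = False
                ) -> TrajectoryEnsemble:
    """Euler-Maruyama ensemble of the OU process.

    ``params`` is an :class:`~dmaxent.ou.OUParams`.  Initial states are drawn
    from the stationary Gaussian N(mu0, sigma0^2/(2 beta0)); with
    ``noise_off`` the diffusion term and initial spread are dropped, leaving
    the deterministic relaxation h(t).
    """
    if dt <= 0 or n_traj < 1:
        raise ValueError("need dt > 0 and n_traj >= 1")
    proto = params.protocol
    sigma0 = params.sigma0
    n_steps, rec = _record_grid(t_end, dt, record_every)
    times = rec * dt
    mu_t = np.empty(n_steps)
    beta_t = np.empty(n_steps)
    for k in range(n_steps):
        mu_t[k], beta_t[k] = proto(k * dt)

    rngs = _spawn_rngs(seed, n_traj)
    paths = np.empty((n_traj, len(rec)))
    init_sd = 0.0 if noise_off else sigma0 / np.sqrt(2.0 * params.beta0)
    for lo in range(0, n_traj, _CHUNK):
        hi = min(lo + _CHUNK, n_traj)
        m = hi - lo
        if noise_off:
            x = np.full(m, params.mu0)
            noise = None
        else:
            draws = np.stack([rngs[i].standard_normal(n_steps + 1)
                              for i in range(lo, hi)])
            x = params.mu0 + init_sd * draws[:, 0]
            noise = draws[:, 1:]
        rec_set = {int(s): j for j, s in enumerate(rec)}
        if 0 in rec_set:
            paths[lo:hi, rec_set[0]] = x
        for k in range(n_steps):
            x = x + beta_t[k] * (mu_t[k] - x) * dt
            if not noise_off:
                x = x + sigma0 * np.sqrt(dt) * noise[:, k]
            j = rec_set.get(k + 1)
            if j is not None:
                paths[lo:hi, j] = x
    return TrajectoryEnsemble(times=times, paths=paths, dt=dt, seed=seed,
                              model="ou", protocol=proto)


def simulate_island(protocol: DriveProtocol, n_traj: int, dt: float,
                    seed: int, t_end: float, init=None,
                    init_states: np.ndarray | None = None,
                    record_every: int = 10, noise_off: bool = False
                    ) -> TrajectoryEnsemble:
    """Euler-Maruyama ensemble of the stochastic logistic island model.

    Steps n <- n + [n(r - lambda n) + m] dt + sqrt(n dt) z, then reflects
    n <- |n| (Euler overshoot below zero is folded back; the true m > 1/2
    process stays positive).  ``init`` gives forces whose stationary
    distribution seeds the ensemble; alternatively pass explicit
    ``init_states``.
    """
    from .island import island_model, _unpack
    if dt <= 0 or n_traj < 1:
        raise ValueError("need dt > 0 and n_traj >= 1")
    model = island_model()
    n_steps, rec = _record_grid(t_end, dt, record_every)
    times = rec * dt
    r_t = np.empty(n_steps)
    lam_t = np.empty(n_steps)
    m_t = np.empty(n_steps)
    for k in range(n_steps):
        r_t[k], lam_t[k], m_t[k] = protocol(k * dt)
    if np.any(lam_t <= 0):
        raise ValueError("lambda must stay positive (explosive drift otherwise)")

    # child 0 seeds the initial states, child i+1 drives trajectory i, so
    # growing n_traj leaves existing trajectories untouched
    rngs = _spawn_rngs(seed, n_traj + 1)
    if init_states is not None:
        x0_all = np.asarray(init_states, dtype=float)
        if len(x0_all) != n_traj:
            raise ValueError("init_states length must equal n_traj")
    elif init is not None:
        x0_all = sample_stationary(model, np.asarray(
            _unpack(init), dtype=float), n_traj, rngs[0])
    else:
        raise ValueError("provide init forces or init_states")

    paths = np.empty((n_traj, len(rec)))
    rec_set = {int(s): j for j, s in enumerate(rec)}
    for lo in range(0, n_traj, _CHUNK):
        hi = min(lo + _CHUNK, n_traj)
        x = x0_all[lo:hi].copy()
        noise = (None if noise_off else
                 np.stack([rngs[i + 1].standard_normal(n_steps)
                           for i in range(lo, hi)]))
        if 0 in rec_set:
            paths[lo:hi, rec_set[0]] = x
        sqdt = np.sqrt(dt)
        for k in range(n_steps):
            x = x + (x * (r_t[k] - lam_t[k] * x) + m_t[k]) * dt
            if not noise_off:
                x = x + np.sqrt(np.abs(x)) * sqdt * noise[:, k]
            np.abs(x, out=x)  # reflect Euler overshoots below zero
            j = rec_set.get(k + 1)
            if j is not None:
                paths[lo:hi, j] = x
    return TrajectoryEnsemble(times=times, paths=paths, dt=dt, seed=seed,
                              model="island", protocol=protocol)


def ensemble_moments(ens: TrajectoryEnsemble, model: ModelSpec):
    """Per-time observable means and standard errors.

    Returns (means, ses), each of shape (d, n_times).  For the island
    observables any zero population value makes <log n> undefined and raises.
    """
    x = ens.paths
    if model.name == "island":
        n_zero = int(np.count_nonzero(x <= 0.0))
        if n_zero:
            raise ValueError(
                f"{n_zero} nonpositive population values present; "
                "<log n> is undefined for this ensemble")
    d = model.dim
    n_traj, n_times = x.shape
    means = np.empty((d, n_times))
    ses = np.empty((d, n_times))
    for j in range(n_times):
        A = model.observables(x[:, j])  # (d, n_traj)
        means[:, j] = A.mean(axis=1)
        ses[:, j] = A.std(axis=1, ddof=1) / np.sqrt(n_traj)
    return means, ses
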