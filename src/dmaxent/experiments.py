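"""Scripted comparisons of DME against its reference solutions.

Three experiment families: an abrupt step in the applied forces, the
forward/backward (ir)reversibility of the effective-force path, and periodic
drives (square wave vs smooth cosine ramps).  Each runs the DME reduction
side by side with the Fokker-Planck reference (and optionally a seeded SDE
ensemble and, for the island model, the birth-death transition-matrix
method), tracks the observables of every method on a shared time grid, and
measures the reduction error by the relative entropy KL(FPE || DME ansatz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import directed_hausdorff

from .core import (GriddedDensity, ModelSpec, integrate_effective_forces,
                   relative_entropy_kl, stationary_density)
from .fpe import build_birth_death, make_grid, scheme_stationary, \
    solve_fpe, solve_master
from .protocols import DriveProtocol
from .simulate import ensemble_moments, simulate_island, simulate_ou

__all__ = [
    "ComparisonReport",
    "DecayWindow",
    "run_step_experiment",
    "run_reversibility_experiment",
    "run_periodic_experiment",
    "analyze_error_decay",
]


@dataclass
class ComparisonReport:
    """Shared-time-grid comparison of DME against reference methods."""

    times: np.ndarray
    observables: dict = field(default_factory=dict)   # method -> (d, n_times)
    ses: dict = field(default_factory=dict)           # method -> (d, n_times)
    kl: np.ndarray | None = None                      # KL(FPE || DME) per time
    alpha_path: np.ndarray | None = None              # effective forces
    applied_path: np.ndarray | None = None
    snapshots: dict = field(default_factory=dict)     # method -> {t: density}
    manifest: dict = field(default_factory=dict)

    def check_complete(self, methods) -> None:
        missing = [m for m in methods if m not in self.observables]
        if missing:
            raise RuntimeError(f"methods missing from report: {missing}")


def _density_observables(model: ModelSpec, dens: GriddedDensity) -> np.ndarray:
    A = model.observables(dens.grid)
    return np.trapezoid(A * dens.values, dens.grid, axis=1)


def _dme_observable_path(model: ModelSpec, alpha_path) -> np.ndarray:
    out = np.empty((model.dim, len(alpha_path)))
    if model.name == "island":
        from .island import island_moments
        for k, a in enumerate(alpha_path):
            out[:, k] = island_moments(a).observable_means
    elif model.name == "ou":
        from .ou import natural_from_alpha
        for k, a in enumerate(alpha_path):
            mu, beta = natural_from_alpha(a)
            sig2 = 1.0 / model.force_scale
            out[:, k] = (mu, mu * mu + sig2 / (2.0 * beta))
    else:
        for k, a in enumerate(alpha_path):
            out[:, k] = _density_observables(
                model, stationary_density(model, a))
    return out


def _shared_times(horizon, dt, n_out):
    n_steps = int(round(horizon / dt))
    every = max(n_steps // max(n_out - 1, 1), 1)
    rec = np.arange(0, n_steps + 1, every)
    if rec[-1] != n_steps:
        rec = np.append(rec, n_steps)
    return rec * dt, every


def _run_methods(model, protocol, alpha_init, times, *, methods, grid,
                 n_traj, dt, record_every, seed, snapshot_times, rtol,
                 N_max=None):
    report = ComparisonReport(times=times)
    report.applied_path = np.stack([protocol(t) for t in times])

    alpha_path = integrate_effective_forces(model, protocol, alpha_init,
                                            times, rtol=rtol)
    report.alpha_path = alpha_path
    report.observables["dme"] = _dme_observable_path(model, alpha_path)
    if snapshot_times:
        report.snapshots["dme"] = {
            t: stationary_density(model, alpha_path[np.argmin(np.abs(times - t))],
                                  grid=grid.centers)
            for t in snapshot_times}

    if "fpe" in methods:
        initial = scheme_stationary(model, grid, alpha_init)
        path = solve_fpe(model, protocol, initial, times, grid=grid)
        report.observables["fpe"] = np.stack(
            [_density_observables(model, d) for d in path], axis=1)
        kl = np.empty(len(times))
        for k, d in enumerate(path):
            ansatz = stationary_density(model, alpha_path[k], grid=grid.centers)
            kl[k] = max(relative_entropy_kl(d, ansatz), 0.0)
        report.kl = kl
        if snapshot_times:
            report.snapshots["fpe"] = {
                t: path[int(np.argmin(np.abs(times - t)))] for t in snapshot_times}

    if "ensemble" in methods:
        if model.name == "island":
            ens = simulate_island(protocol, n_traj, dt, seed, times[-1],
                                  init=alpha_init, record_every=record_every)
        else:
            from .ou import OUParams, natural_from_alpha
            mu0, beta0 = natural_from_alpha(alpha_init)
            params = OUParams(protocol=DriveProtocol.custom(
                lambda t, p=protocol: np.asarray(
                    natural_from_alpha(p(t))),
                switch_times=protocol.switch_times),
                sigma0=float(np.sqrt(1.0 / model.force_scale)),
                mu0=mu0, beta0=beta0)
            ens = simulate_ou(params, n_traj, dt, seed, times[-1],
                              record_every=record_every)
        if not np.allclose(ens.times, times, atol=1e-9):
            raise RuntimeError("ensemble time grid out of sync")
        means, ses = ensemble_moments(ens, model)
        report.observables["ensemble"] = means
        report.ses["ensemble"] = ses

    if "matrix" in methods:
        if model.name != "island":
            raise ValueError("transition-matrix method applies to the island model")
        if N_max is None:
            N_max = int(np.ceil(grid.hi))
        p0 = build_birth_death(alpha_init, N_max).stationary()
        pmf_path = solve_master(protocol, p0, times, N_max=N_max)
        ns = np.arange(N_max + 1, dtype=float)
        logn = np.where(ns > 0, np.log(np.where(ns > 0, ns, 1.0)), 0.0)
        obs = np.stack([pmf_path @ ns,
                        -(pmf_path @ ns**2) / 2.0,
                        pmf_path[:, 1:] @ logn[1:]], axis=0)
        report.observables["matrix"] = obs
        if snapshot_times:
            report.snapshots["matrix"] = {
                t: pmf_path[int(np.argmin(np.abs(times - t)))]
                for t in snapshot_times}
    report.check_complete(methods)
    return report


def run_step_experiment(model: ModelSpec, alpha0, alpha1, horizon: float,
                        methods=("dme", "fpe"), n_out: int = 81,
                        dt: float = 0.01, n_traj: int = 3000, seed: int = 0,
                        snapshot_times=(), fpe_cells: int = 400,
                        N_max: int | None = None,
                        rtol: float = 1e-8) -> ComparisonReport:
    """Abrupt change alpha0 -> alpha1 at t = 0 from a stationary start."""
    alpha0 = np.asarray(alpha0, dtype=float)
    alpha1 = np.asarray(alpha1, dtype=float)
    model.check_valid(alpha0)
    model.check_valid(alpha1)
    protocol = DriveProtocol.step(alpha0, alpha1, t_switch=0.0)
    times, every = _shared_times(horizon, dt, n_out)
    grid = make_grid(model, [alpha0, alpha1], fpe_cells)
    report = _run_methods(model, protocol, alpha0, times, methods=methods,
                          grid=grid, n_traj=n_traj, dt=dt, record_every=every,
                          seed=seed, snapshot_times=tuple(snapshot_times),
                          rtol=rtol, N_max=N_max)
    report.manifest = {
        "experiment": "step", "model": model.name,
        "alpha0": alpha0.tolist(), "alpha1": alpha1.tolist(),
        "horizon": horizon, "dt": dt, "n_traj": n_traj, "seed": seed,
        "fpe_cells": fpe_cells, "rtol": rtol, "methods": list(methods),
    }
    return report


@dataclass
class ReversibilityResult:
    times: np.ndarray
    forward: np.ndarray    # (n_times, d) effective forces alpha0 -> alpha1
    backward: np.ndarray   # (n_times, d) effective forces alpha1 -> alpha0
    hausdorff: float       # distance between the 2D (dims 0,1) projections


def run_reversibility_experiment(model: ModelSpec, alpha0, alpha1,
                                 horizon: float, n_out: int = 201,
                                 dims=(0, 1),
                                 rtol: float = 1e-8) -> ReversibilityResult:
    """Run alpha0 -> alpha1 and alpha1 -> alpha0, both from stationarity.

    The hysteresis metric is the symmetric Hausdorff distance between the two
    projected paths; a reversible flow would retrace itself and give ~0.
    """
    times = np.linspace(0.0, horizon, n_out)
    fwd = integrate_effective_forces(
        model, DriveProtocol.constant(alpha1), alpha0, times, rtol=rtol)
    bwd = integrate_effective_forces(
        model, DriveProtocol.constant(alpha0), alpha1, times, rtol=rtol)
    a = fwd[:, list(dims)]
    b = bwd[:, list(dims)]
    h = max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])
    return ReversibilityResult(times=times, forward=fwd, backward=bwd,
                               hausdorff=h)


def run_periodic_experiment(model: ModelSpec, protocol: DriveProtocol,
                            horizon: float, alpha_init,
                            methods=("dme", "fpe"), n_out: int = 161,
                            dt: float = 0.01, n_traj: int = 3000,
                            seed: int = 0, fpe_cells: int = 400,
                            rtol: float = 1e-8) -> ComparisonReport:
    """Periodic drive from a stationary start at ``alpha_init``.

    Adds to the report the instantaneous-equilibrium observables (stationary
    moments at the momentary applied forces) and a lag estimate of the DME
    mean behind that equilibrium mean (cross-correlation phase shift).
    """
    alpha_init = np.asarray(alpha_init, dtype=float)
    times, every = _shared_times(horizon, dt, n_out)
    levels = list(protocol.levels) + [alpha_init]
    grid = make_grid(model, levels, fpe_cells)
    report = _run_methods(model, protocol, alpha_init, times, methods=methods,
                          grid=grid, n_traj=n_traj, dt=dt, record_every=every,
                          seed=seed, snapshot_times=(), rtol=rtol)
    report.observables["equilibrium"] = _dme_observable_path(
        model, report.applied_path)

    x = report.observables["dme"][0] - report.observables["dme"][0].mean()
    y = report.observables["equilibrium"][0] - \
        report.observables["equilibrium"][0].mean()
    if np.ptp(y) > 0:
        lags = np.arange(-(len(x) - 1), len(x))
        cc = np.correlate(x, y, mode="full")
        lag = float(lags[np.argmax(cc)] * (times[1] - times[0]))
    else:
        lag = 0.0
    report.manifest = {
        "experiment": "periodic", "model": model.name,
        "protocol": protocol.kind, "period": protocol.period,
        "horizon": horizon, "dt": dt, "seed": seed, "rtol": rtol,
        "lag_of_dme_mean": lag, "methods": list(methods),
    }
    return report


@dataclass
class DecayWindow:
    """Exponential-fit summary of one post-switch KL relaxation window."""

    t_start: float
    t_end: float
    rate: float
    r_squared: float
    nonmonotonic: bool


def analyze_error_decay(times, kl, switch_times, drop_factor: float = 10.0,
                        noise_floor: float = 1e-12,
                        min_samples: int = 5) -> list[DecayWindow]:
    """Fit the early exponential drop of KL(t) after each force switch.

    For each window between consecutive switch times, log KL is regressed on
    t from the post-switch KL maximum (the divergence first builds up as the
    system is pushed out of equilibrium, then relaxes) until KL first falls by
    ``drop_factor``; afterwards any local increase above the noise floor
    raises the non-monotonicity flag.
    """
    times = np.asarray(times, dtype=float)
    kl = np.asarray(kl, dtype=float)
    edges = sorted(set(float(s) for s in switch_times))
    edges = [e for e in edges if times[0] <= e < times[-1]] or [times[0]]
    windows = list(zip(edges, edges[1:] + [times[-1]]))
    out = []
    for t0, t1 in windows:
        sel = (times >= t0) & (times <= t1) & (kl > noise_floor)
        tw, kw = times[sel], kl[sel]
        if len(tw) < min_samples:
            raise ValueError(
                f"window [{t0:.4g}, {t1:.4g}] has {len(tw)} usable samples "
                f"(< {min_samples})")
        start = int(np.argmax(kw))
        tw, kw = tw[start:], kw[start:]
        if len(tw) < min_samples:
            raise ValueError(
                f"window [{t0:.4g}, {t1:.4g}] has {len(tw)} samples after "
                f"the KL peak (< {min_samples})")
        k0 = kw[0]
        below = np.nonzero(kw <= k0 / drop_factor)[0]
        stop = below[0] + 1 if len(below) else len(kw)
        # the initial drop also ends where KL turns around (non-monotone
        # relaxation): never fit past the minimum of the remaining series
        stop = min(stop, int(np.argmin(kw)) + 1)
        stop = max(stop, min_samples)
        fit = stats.linregress(tw[:stop], np.log(kw[:stop]))
        after = kw[stop - 1:]
        nonmono = bool(np.any(np.diff(after) > noise_floor
                              + 1e-6 * after[:-1]))
        out.append(DecayWindow(t_start=float(t0), t_end=float(t1),
                               rate=float(-fit.slope),
                               r_squared=float(fit.rvalue**2),
                               nonmonotonic=nonmono))
    return out
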