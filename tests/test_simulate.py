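"""Euler-Maruyama ensembles: determinism, deterministic limits, stationary
behaviour and agreement with analytic moments."""

import numpy as np
import pytest
from scipy import integrate, stats

import dmaxent as dm
from dmaxent.island import G, island_moments
from dmaxent.ou import OUParams, ou_closed_form_moments
from dmaxent.protocols import DriveProtocol
from dmaxent.simulate import (ensemble_moments, sample_stationary,
                              simulate_island, simulate_ou)


# ------------------------------------------------------------------ OU SDE

def test_noise_off_reproduces_deterministic_relaxation():
    params = OUParams.step_change(0.1, 0.45, 1.0, 0.7, 0.1)
    ens = simulate_ou(params, 3, 0.001, 0, 5.0, noise_off=True)
    h = 1.0 + (0.1 - 1.0) * np.exp(-0.7 * ens.times)
    assert np.max(np.abs(ens.paths - h)) < 5e-4  # O(dt) Euler error
    assert np.all(ens.paths[0] == ens.paths[1])


def test_ou_ensemble_mean_matches_closed_form(ou_step):
    params = OUParams.step_change(0.1, 0.45, ou_step["mu_inf"],
                                  ou_step["beta_inf"], ou_step["sigma0"])
    ens = simulate_ou(params, 3000, 0.01, 123, 2.0, record_every=100)
    m_ref, v_ref = ou_closed_form_moments(0.1, 0.45, 1.0, 0.7, 0.1,
                                          ens.times)
    mean = ens.paths.mean(axis=0)
    se = ens.paths.std(axis=0, ddof=1) / np.sqrt(ens.n_traj)
    assert np.all(np.abs(mean - m_ref) < 3 * se + 2e-4)


def test_identical_seeds_identical_ensembles(ou_step):
    params = OUParams.step_change(0.6, 0.5, 1.0, 0.7, 0.1)
    a = simulate_ou(params, 64, 0.01, 99, 1.0)
    b = simulate_ou(params, 64, 0.01, 99, 1.0)
    assert np.array_equal(a.paths, b.paths)
    c = simulate_ou(params, 64, 0.01, 100, 1.0)
    assert not np.array_equal(a.paths, c.paths)


# -------------------------------------------------------------- island SDE

def test_absorbing_state_without_immigration():
    proto = DriveProtocol.constant([0.1, 0.002, 0.0])
    ens = simulate_island(proto, 4, 0.01, 1, 2.0,
                          init_states=np.zeros(4))
    assert np.all(ens.paths == 0.0)


def test_noise_off_matches_logistic_immigration_ode():
    a = np.array([0.1, 0.002, 3.0])
    proto = DriveProtocol.constant(a)
    ens = simulate_island(proto, 2, 0.001, 0, 20.0, noise_off=True,
                          init_states=np.array([5.0, 5.0]))
    sol = integrate.solve_ivp(
        lambda t, n: n * (0.1 - 0.002 * n) + 3.0, (0, 20.0), [5.0],
        t_eval=ens.times, rtol=1e-10, atol=1e-12)
    assert np.max(np.abs(ens.paths[0] - sol.y[0])) < 5e-3


def test_island_prefix_stable_when_growing_the_ensemble():
    a = np.array([0.1, 0.002, 3.0])
    proto = DriveProtocol.constant(a)
    big = simulate_island(proto, 40, 0.01, 42, 1.0, init=a)
    small = simulate_island(proto, 25, 0.01, 42, 1.0, init=a)
    assert np.array_equal(big.paths[:25], small.paths)


def test_stationary_ensemble_shows_no_drift():
    """Stationary start + constant forces: the ensemble mean of n stays flat
    (regression slope indistinguishable from zero at 3 SE)."""
    a = np.array([0.1, 0.002, 3.0])
    proto = DriveProtocol.constant(a)
    ens = simulate_island(proto, 1200, 0.01, 7, 40.0, init=a,
                          record_every=100)
    mean = ens.paths.mean(axis=0)
    fit = stats.linregress(ens.times, mean)
    assert abs(fit.slope) < 3 * fit.stderr + 1e-4
    stat_mean = island_moments(a).n
    se = ens.paths.std(axis=0, ddof=1).mean() / np.sqrt(ens.n_traj)
    assert abs(mean.mean() - stat_mean) < 3 * se


def test_weak_convergence_under_dt_halving():
    a0 = np.array([0.05, 0.005, 1.0])
    a1 = np.array([0.1, 0.002, 3.0])
    proto = DriveProtocol.step(a0, a1)
    coarse = simulate_island(proto, 6000, 0.01, 3, 5.0, init=a0,
                             record_every=500)
    fine = simulate_island(proto, 6000, 0.005, 3, 5.0, init=a0,
                           record_every=1000)
    se = coarse.paths[:, -1].std(ddof=1) / np.sqrt(6000)
    assert abs(coarse.paths[:, -1].mean() - fine.paths[:, -1].mean()) < se


# ------------------------------------------------------ stationary sampling

def test_ou_stationary_samples_match_gaussian_moments(ou):
    from dmaxent.ou import alpha_from_natural
    alpha = alpha_from_natural(1.0, 0.7)
    x = sample_stationary(ou, alpha, 20000, 5)
    se_m = x.std(ddof=1) / np.sqrt(len(x))
    assert abs(x.mean() - 1.0) < 3 * se_m
    v_ref = 0.1**2 / (2 * 0.7)
    assert x.var(ddof=1) == pytest.approx(v_ref, rel=0.05)


def test_island_stationary_samples_match_analytic_cdf(island, island_step):
    a = island_step["alpha1"]
    x = sample_stationary(island, a, 10000, 11)
    dens = dm.stationary_density(island, a)
    cdf = np.concatenate([[0.0], np.cumsum(
        0.5 * (dens.values[1:] + dens.values[:-1]) * np.diff(dens.grid))])
    cdf /= cdf[-1]
    emp = np.searchsorted(np.sort(x), dens.grid) / len(x)
    assert np.max(np.abs(emp - cdf)) < 0.02
    assert np.array_equal(x, sample_stationary(island, a, 10000, 11))


# --------------------------------------------------------- ensemble moments

def test_constant_ensemble_has_zero_standard_error(island):
    from dmaxent.simulate import TrajectoryEnsemble
    paths = np.full((10, 4), 7.0)
    ens = TrajectoryEnsemble(times=np.arange(4.0), paths=paths, dt=0.1,
                             seed=0, model="island")
    means, ses = ensemble_moments(ens, island)
    assert np.allclose(ses, 0.0)
    assert np.allclose(means[0], 7.0)


def test_second_moment_dominates_squared_mean(island, island_step):
    proto = DriveProtocol.constant(island_step["alpha1"])
    ens = simulate_island(proto, 300, 0.01, 2, 2.0,
                          init=island_step["alpha1"])
    means, _ = ensemble_moments(ens, island)
    n2 = -2.0 * means[1]
    assert np.all(n2 >= means[0] ** 2)


def test_log_moment_rejects_extinct_trajectories(island):
    from dmaxent.simulate import TrajectoryEnsemble
    paths = np.array([[1.0, 0.0], [2.0, 3.0]])
    ens = TrajectoryEnsemble(times=np.arange(2.0), paths=paths, dt=0.1,
                             seed=0, model="island")
    with pytest.raises(ValueError, match="nonpositive"):
        ensemble_moments(ens, island)
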