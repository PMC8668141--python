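"""Generic DME engine: stationary densities, partition function, moments,
relative entropy, the effective-force ODE and the moment projection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dmaxent as dm
from dmaxent.core import GriddedDensity, SupportMismatchError
from dmaxent.island import island_moments, stationary_mode, G, H
from dmaxent.ou import alpha_from_natural, natural_from_alpha, ou_dme_rhs
from dmaxent.protocols import DriveProtocol


# ---------------------------------------------------------------- densities

def test_ou_stationary_density_is_the_gaussian(ou):
    alpha = alpha_from_natural(1.0, 0.7)
    dens = dm.stationary_density(ou, alpha)
    x = dens.grid
    v = 0.1**2 / (2 * 0.7)
    ref = np.exp(-(x - 1.0) ** 2 / (2 * v)) / np.sqrt(2 * np.pi * v)
    assert dens.mass == pytest.approx(1.0, abs=1e-9)
    assert np.max(np.abs(dens.values - ref)) < 1e-6 * ref.max()


def test_island_stationary_density_closed_form_at_zero_growth(island):
    # r = 0, lambda = 1, m = 1: u(n) = 2 n exp(-n^2), Z = 1/2
    alpha = np.array([0.0, 1.0, 1.0])
    dens = dm.stationary_density(island, alpha, n_points=8001)
    ref = 2.0 * dens.grid * np.exp(-dens.grid**2)
    assert np.max(np.abs(dens.values - ref)) < 1e-6
    assert dm.log_partition(island, alpha) == pytest.approx(np.log(0.5),
                                                            abs=1e-9)


def test_island_density_mass_and_mode(island, island_step):
    alpha = island_step["alpha1"]
    dens = dm.stationary_density(island, alpha, n_points=4001)
    assert abs(dens.mass - 1.0) < 1e-8
    mode = stationary_mode(alpha)
    r, lam, m = alpha
    assert mode == pytest.approx(
        (r + np.sqrt(r**2 + 2 * lam * (2 * m - 1))) / (2 * lam), rel=1e-12)
    grid_mode = dens.grid[np.argmax(dens.values)]
    assert abs(grid_mode - mode) < dens.grid[-1] / 200


def test_invalid_forces_raise(island, ou):
    with pytest.raises(dm.ValidityError, match="m = 0.4"):
        dm.stationary_density(island, np.array([0.1, 0.002, 0.4]))
    with pytest.raises(dm.ValidityError, match="lambda"):
        dm.stationary_density(island, np.array([0.1, -1.0, 3.0]))
    with pytest.raises(dm.ValidityError, match="beta"):
        dm.stationary_density(ou, np.array([1.0, 0.5]))


# ----------------------------------------------------------- log partition

def test_ou_log_partition_matches_gaussian_normalization(ou):
    # int exp[(2 mu beta x - beta x^2)/sigma0^2] dx
    #   = exp(beta mu^2/sigma0^2) sqrt(pi sigma0^2/beta)
    mu, beta, s0 = 1.0, 0.7, 0.1
    expected = beta * mu**2 / s0**2 + 0.5 * np.log(np.pi * s0**2 / beta)
    assert dm.log_partition(ou, alpha_from_natural(mu, beta)) == \
        pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("model_name,alpha", [
    ("ou", None), ("island", np.array([0.1, 0.002, 3.0]))])
def test_log_partition_generates_moments(model_name, alpha, ou, island):
    """Central differences of log Z in the exponent coordinates reproduce
    <A_j> (the generating-function identity)."""
    model = ou if model_name == "ou" else island
    if alpha is None:
        alpha = alpha_from_natural(1.0, 0.7)
    s = model.force_scale
    mom = dm.moments_of(model, alpha)
    for i in range(model.dim):
        h = 1e-4 * max(abs(alpha[i]), 1e-3)
        e = np.zeros(model.dim)
        e[i] = h
        fd = (dm.log_partition(model, alpha + e)
              - dm.log_partition(model, alpha - e)) / (2 * h * s)
        assert fd == pytest.approx(mom[i], rel=1e-6)


# ----------------------------------------------------------------- moments

def test_ou_moments_closed_form(ou):
    mom = dm.moments_of(ou, alpha_from_natural(1.0, 0.7))
    assert mom[0] == pytest.approx(1.0, rel=1e-9)
    assert mom[1] == pytest.approx(1.0 + 0.01 / 1.4, rel=1e-9)


def test_island_moments_match_hypergeometric_ratios(island, island_step):
    alpha = island_step["alpha1"]
    mom = dm.moments_of(island, alpha)
    G0 = G(0, alpha)
    assert mom[0] == pytest.approx(G(1, alpha) / G0, rel=1e-8)
    assert mom[1] == pytest.approx(-G(2, alpha) / (2 * G0), rel=1e-8)
    assert mom[2] == pytest.approx(H(0, 1, alpha) / G0, rel=1e-8)


def test_moments_of_symmetric_gridded_density(ou):
    x = np.linspace(-8, 8, 4001)
    dens = GriddedDensity(x, np.exp(-x**2 / 2)).normalized()
    mom = dm.moments_of(ou, dens)
    assert abs(mom[0]) < 1e-12
    assert mom[1] == pytest.approx(1.0, rel=1e-6)


# --------------------------------------------------------- relative entropy

def _gaussian(grid, mu, var):
    return GriddedDensity(
        grid, np.exp(-(grid - mu) ** 2 / (2 * var))).normalized()


def test_kl_identity_and_gaussian_closed_form():
    x = np.linspace(-10, 11, 6001)
    p = _gaussian(x, 0.0, 1.0)
    assert dm.relative_entropy_kl(p, p) == pytest.approx(0.0, abs=1e-12)
    q = _gaussian(x, 1.0, 1.0)
    assert dm.relative_entropy_kl(p, q) == pytest.approx(0.5, abs=1e-6)


def test_kl_support_mismatch_raises():
    x = np.linspace(-5, 5, 1001)
    p = _gaussian(x, 0.0, 1.0)
    q_vals = np.where(x > 0, np.exp(-x**2), 0.0)
    q = GriddedDensity(x, q_vals)
    with pytest.raises(SupportMismatchError):
        dm.relative_entropy_kl(p, GriddedDensity(x, q.values / q.mass))


@given(mu=st.floats(-1.0, 1.0), dv=st.floats(0.6, 1.7))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_kl_nonnegative_and_zero_iff_equal(mu, dv):
    x = np.linspace(-14, 14, 4001)
    p = _gaussian(x, 0.0, 1.0)
    q = _gaussian(x, mu, dv)
    kl = dm.relative_entropy_kl(p, q)
    assert kl >= -1e-10
    closed = 0.5 * (1.0 / dv + mu**2 / dv - 1.0 + np.log(dv))
    assert kl == pytest.approx(closed, abs=5e-5)
    if abs(mu) > 0.05 or abs(dv - 1) > 0.05:
        assert kl > 1e-4 * min(1.0, mu**2 + (dv - 1) ** 2)


# ------------------------------------------------------------- DME dynamics

def test_dme_rhs_vanishes_at_fixed_point(ou, island, island_step):
    a = alpha_from_natural(0.7, 1.3)
    assert np.allclose(dm.dme_rhs(ou, a, a), 0.0, atol=1e-12)
    a1 = island_step["alpha1"]
    assert np.allclose(dm.dme_rhs(island, a1, a1), 0.0, atol=1e-12)


def test_generic_engine_matches_decoupled_ou_form(ou):
    """The generic linear-solve rhs agrees with the explicit decoupled
    (mu*, beta*) equations mapped to exponent coordinates."""
    eff_nat = (0.5, 0.6)
    app_nat = (1.0, 0.7)
    y = dm.dme_rhs(ou, alpha_from_natural(*eff_nat),
                   alpha_from_natural(*app_nat))
    dmu, dbeta = ou_dme_rhs(*eff_nat, *app_nat)
    mu_s, beta_s = eff_nat
    expected = np.array([2 * (beta_s * dmu + mu_s * dbeta), -dbeta])
    assert np.allclose(y, expected, atol=1e-10)


def test_island_rhs_linear_solve_vs_dense_inverse(island, island_step):
    eff = np.array([0.05, 0.005, 1.0])
    mats = dm.moment_matrices(island, eff)
    y = dm.dme_rhs(island, eff, island_step["alpha1"])
    y_inv = np.linalg.inv(mats.C) @ (mats.B @ (island_step["alpha1"] - eff))
    assert np.all(np.isfinite(y))
    assert np.allclose(y, y_inv, atol=1e-10 * max(1, np.abs(y).max()))


@pytest.mark.parametrize("model_name", ["ou", "island"])
def test_stationarity_identity_at_random_force_points(model_name, ou, island):
    """B alpha + V/2 = 0 under the stationary density: the quasi-stationary
    closure is exact at its own fixed point, at 20+ random force points."""
    rng = np.random.default_rng(11)
    model = ou if model_name == "ou" else island
    for _ in range(20):
        if model_name == "ou":
            alpha = alpha_from_natural(rng.uniform(-2, 2),
                                       rng.uniform(0.1, 3.0))
        else:
            alpha = np.array([rng.uniform(-0.2, 0.3),
                              rng.uniform(5e-4, 0.05),
                              rng.uniform(0.6, 5.0)])
        mats = dm.moment_matrices(model, alpha)
        resid = mats.B @ alpha + mats.V / 2
        scale = max(np.abs(mats.B @ alpha).max(), 1e-3)
        assert np.max(np.abs(resid)) < 1e-8 * scale


@pytest.mark.parametrize("model_name", ["ou", "island"])
def test_sensitivity_matrix_is_spd(model_name, ou, island):
    rng = np.random.default_rng(5)
    model = ou if model_name == "ou" else island
    for _ in range(10):
        if model_name == "ou":
            alpha = alpha_from_natural(rng.uniform(-2, 2),
                                       rng.uniform(0.1, 3.0))
        else:
            alpha = np.array([rng.uniform(-0.2, 0.3),
                              rng.uniform(5e-4, 0.05),
                              rng.uniform(0.6, 5.0)])
        mats = dm.moment_matrices(model, alpha)
        assert np.allclose(mats.C, mats.C.T)
        w = np.linalg.eigvalsh(mats.C)
        assert w[0] > -1e-10 * abs(w[-1])


# ----------------------------------------------------- ODE integration

def test_constant_protocol_stays_at_equilibrium(island, island_step):
    a = island_step["alpha1"]
    times = np.linspace(0, 10, 11)
    path = dm.integrate_effective_forces(
        island, DriveProtocol.constant(a), a, times)
    assert np.max(np.abs(path - a)) < 1e-9


def test_ou_step_integration_matches_closed_form(ou, ou_step):
    mu0, beta0 = 0.1, 0.45
    a0 = alpha_from_natural(mu0, beta0)
    a1 = alpha_from_natural(ou_step["mu_inf"], ou_step["beta_inf"])
    times = np.linspace(0, 10, 101)
    path = dm.integrate_effective_forces(
        ou, DriveProtocol.step(a0, a1), a0, times)
    m = np.array([natural_from_alpha(a)[0] for a in path])
    v = ou_step["sigma0"]**2 / (2 * np.array([natural_from_alpha(a)[1]
                                           for a in path]))
    m_ref = ou_step["mu_inf"] + (mu0 - ou_step["mu_inf"]) * np.exp(
        -ou_step["beta_inf"] * times)
    v0 = ou_step["sigma0"]**2 / (2 * beta0)
    v_inf = ou_step["sigma0"]**2 / (2 * ou_step["beta_inf"])
    v_ref = v0 * np.exp(-2 * ou_step["beta_inf"] * times) + v_inf * (
        1 - np.exp(-2 * ou_step["beta_inf"] * times))
    assert np.max(np.abs(m - m_ref)) < 1e-6
    assert np.max(np.abs(v - v_ref)) < 1e-6


def test_island_fixed_point_reached_on_its_own_timescale(island, island_step):
    """Under constant applied forces the effective forces converge; the
    slowest relaxation eigenvalue at the target (~0.17/time) sets the
    horizon needed for 1e-6 accuracy (t ~ 120), and the distance decreases
    monotonically after the initial transient."""
    a0, a1 = island_step["alpha0"], island_step["alpha1"]
    times = np.linspace(0, 120, 61)
    path = dm.integrate_effective_forces(
        island, DriveProtocol.constant(a1), a0, times)
    dist = np.linalg.norm(path - a1, axis=1)
    assert dist[-1] < 1e-6
    tail = dist[times >= 20]
    assert np.all(np.diff(tail) < 1e-12)


def test_validity_violation_reports_time(island):
    # drive m below the threshold: the integration must abort with the time
    a0 = np.array([0.1, 0.002, 0.6])
    bad = np.array([0.1, 0.002, -2.0])

    def drive(t):
        return bad

    proto = DriveProtocol.custom(drive)
    with pytest.raises(dm.ValidityError, match="t="):
        dm.integrate_effective_forces(island, proto, a0,
                                      np.linspace(0, 50, 11))


# ----------------------------------------------------------- projection

def test_projection_round_trip_island(island, island_step):
    a_true = island_step["alpha1"]
    target = island_moments(a_true).observable_means
    rec = dm.project_to_forces(island, target, island_step["alpha0"])
    resid = dm.moments_of(island, rec) - target
    assert np.max(np.abs(resid) / (1 + np.abs(target))) < 1e-8
    assert np.allclose(rec, a_true, rtol=1e-4)


def test_projection_closed_form_ou(ou):
    # target (m, v) inverts to mu* = m, beta* = sigma0^2/(2v)
    m, v = 0.4, 0.004
    target = np.array([m, v + m**2])
    rec = dm.project_to_forces(ou, target, alpha_from_natural(1.0, 1.0))
    mu_s, beta_s = natural_from_alpha(rec)
    assert mu_s == pytest.approx(m, abs=1e-7)
    assert beta_s == pytest.approx(0.1**2 / (2 * v), rel=1e-6)
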