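"""OU model: exact Gaussian dynamics, closed-form DME matrices, and the
central exactness property of the reduction."""

import numpy as np
import pytest

import dmaxent as dm
from dmaxent.ou import (OUParams, alpha_from_natural, natural_from_alpha,
                        ou_closed_form_moments, ou_dme_rhs, ou_dme_solution,
                        ou_exact_moments, ou_matrices, ou_model)
from dmaxent.protocols import DriveProtocol


def _step_params(ou_step, ic_index):
    mu0, beta0 = ou_step["initials"][ic_index]
    return OUParams.step_change(mu0, beta0, ou_step["mu_inf"], ou_step["beta_inf"],
                                ou_step["sigma0"])


# ----------------------------------------------------------- exact moments

def test_initial_condition_is_the_stationary_gaussian(ou_step):
    params = _step_params(ou_step, 2)
    state = ou_exact_moments(params, [0.0])[0]
    assert state.m == pytest.approx(0.1)
    assert state.v == pytest.approx(0.1**2 / (2 * 0.45))


def test_mean_relaxes_to_the_applied_target(ou_step):
    params = _step_params(ou_step, 2)
    states = ou_exact_moments(params, [0.0, 20.0])
    assert states[-1].m == pytest.approx(ou_step["mu_inf"], abs=1e-6)
    assert states[-1].v == pytest.approx(
        ou_step["sigma0"]**2 / (2 * ou_step["beta_inf"]), rel=1e-6)


def test_ode_route_agrees_with_closed_form(ou_step):
    params = _step_params(ou_step, 1)
    closed = ou_exact_moments(params, [2.0], method="closed")[0]
    ode = ou_exact_moments(params, [0.0, 2.0], method="ode")[-1]
    assert ode.m == pytest.approx(closed.m, abs=1e-8)
    assert ode.v == pytest.approx(closed.v, abs=1e-8)


def test_gaussian_state_fgh_view():
    state = dm.GaussianState(m=0.3, v=0.02)
    assert state.h == 0.3
    assert state.g == pytest.approx(1 / 0.04)
    # f is the normalization of f*exp(-g (x-h)^2)
    assert state.f == pytest.approx(np.sqrt(state.g / np.pi), rel=1e-12)


# ------------------------------------------------------------ DME matrices

def test_matrices_at_centered_unit_parameters():
    mats = ou_matrices(0.0, 1.0, 1.0)
    assert np.allclose(mats.B, [[0.5, 0.0], [0.0, 1.0]])
    assert np.allclose(mats.C, [[0.5, 0.0], [0.0, 0.5]])


def test_sensitivity_matrix_matches_quadrature_covariance(ou):
    mu_s, beta_s, s0 = 0.8, 0.55, 0.1
    mats = ou_matrices(mu_s, beta_s, s0)
    from dmaxent.core import covariance_of
    cov = covariance_of(ou, alpha_from_natural(mu_s, beta_s))
    assert np.allclose(mats.C, cov / s0**2, rtol=1e-8)


def test_printed_inverse_is_the_inverse():
    mu_s, beta_s, s0 = 0.8, 0.55, 0.1
    mats = ou_matrices(mu_s, beta_s, s0)
    C_inv = (2 * beta_s / s0**2) * np.array(
        [[4 * beta_s * mu_s**2 + s0**2, -2 * mu_s * beta_s],
         [-2 * mu_s * beta_s, beta_s]])
    assert np.allclose(mats.C @ C_inv, np.eye(2), atol=1e-10)


# ----------------------------------------------------------------- DME rhs

def test_rhs_at_fixed_point_and_hand_value():
    assert ou_dme_rhs(1.0, 0.7, 1.0, 0.7) == (0.0, 0.0)
    dmu, dbeta = ou_dme_rhs(0.1, 0.45, 1.0, 0.7)
    assert dmu == pytest.approx(0.63)
    assert dbeta == pytest.approx(0.225)


def test_rhs_equals_generic_engine_at_random_points(ou):
    rng = np.random.default_rng(17)
    for _ in range(20):
        mu_s, beta_s = rng.uniform(-2, 2), rng.uniform(0.1, 3)
        mu_t, beta_t = rng.uniform(-2, 2), rng.uniform(0.1, 3)
        y = dm.dme_rhs(ou, alpha_from_natural(mu_s, beta_s),
                       alpha_from_natural(mu_t, beta_t))
        dmu, dbeta = ou_dme_rhs(mu_s, beta_s, mu_t, beta_t)
        expected = np.array([2 * (beta_s * dmu + mu_s * dbeta), -dbeta])
        assert np.allclose(y, expected, atol=1e-10 * max(1, abs(dmu), abs(dbeta)))


# ------------------------------------------------------------ DME solution

def test_constant_protocol_keeps_the_initial_state():
    params = OUParams.constant(0.5, 0.8, 0.1)
    times = np.linspace(0, 5, 11)
    mu_s, beta_s, states = ou_dme_solution(params, times)
    assert np.allclose(mu_s, 0.5, atol=1e-9)
    assert np.allclose(beta_s, 0.8, atol=1e-9)


def test_exactness_for_the_step_scenario_all_initial_conditions(ou_step):
    """The reduction reproduces the exact Gaussian mean and variance to
    integration tolerance for every initial condition of the step change."""
    times = np.linspace(0, 10, 201)
    for ic in range(3):
        params = _step_params(ou_step, ic)
        _, _, states = ou_dme_solution(params, times)
        exact = ou_exact_moments(params, times)
        m_err = max(abs(s.m - e.m) for s, e in zip(states, exact))
        v_err = max(abs(s.v - e.v) for s, e in zip(states, exact))
        assert m_err < 1e-6
        assert v_err < 1e-6


def test_exactness_for_smooth_and_ramp_protocols():
    """Exactness holds for arbitrary drive protocols, not just steps."""
    sigma0 = 0.1

    def natural(t):
        return np.array([0.5 + 0.3 * np.sin(0.8 * t), 0.6 + 0.2 * np.cos(t)])

    proto = DriveProtocol.custom(natural)
    params = OUParams(protocol=proto, sigma0=sigma0, mu0=0.2, beta0=0.5)
    times = np.linspace(0, 12, 121)
    _, _, states = ou_dme_solution(params, times, rtol=1e-10, atol=1e-12)
    exact = ou_exact_moments(params, times, method="ode")
    assert max(abs(s.m - e.m) for s, e in zip(states, exact)) < 1e-6
    assert max(abs(s.v - e.v) for s, e in zip(states, exact)) < 1e-6


def test_force_path_is_independent_of_noise_magnitude(ou_step):
    times = np.linspace(0, 8, 81)
    paths = []
    for s0 in (0.05, 0.1, 0.5):
        params = OUParams.step_change(0.1, 0.45, ou_step["mu_inf"],
                                      ou_step["beta_inf"], s0)
        mu_s, beta_s, _ = ou_dme_solution(params, times, rtol=1e-11,
                                          atol=1e-13)
        paths.append(np.column_stack([mu_s, beta_s]))
    assert np.max(np.abs(paths[0] - paths[1])) < 1e-10
    assert np.max(np.abs(paths[1] - paths[2])) < 1e-10


def test_natural_alpha_round_trip():
    mu, beta = -0.7, 1.9
    assert natural_from_alpha(alpha_from_natural(mu, beta)) == \
        pytest.approx((mu, beta))
    with pytest.raises(dm.ValidityError):
        natural_from_alpha(np.array([1.0, 0.5]))
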