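import numpy as np
import pytest

from activecolony.theory import (
    MaterialParams,
    RadialGrowthProfile,
    alignment_rate_1d,
    alignment_rate_2d,
    bulk_order_fixed_point,
    hubble_prediction,
    m_to_um,
    per_min_to_per_s,
    per_s_to_per_min,
    screening_length,
    stress_profile_1d,
    stress_profile_curvature,
    stress_propagation_length,
    torque_1d,
    turbulence_control_parameter,
    um_to_m,
)


def test_unit_converters_roundtrip():
    assert np.isclose(per_s_to_per_min(per_min_to_per_s(0.014)), 0.014)
    assert np.isclose(m_to_um(um_to_m(3.5)), 3.5)


def test_material_params_validation():
    with pytest.raises(ValueError):
        MaterialParams(G=-1.0)
    with pytest.raises(ValueError):
        MaterialParams(Lambda=0.0)


def test_hubble_prediction_is_half_lambda():
    assert hubble_prediction(0.014) == 0.007
    with pytest.raises(ValueError):
        hubble_prediction(-1.0)


def test_stress_propagation_length_plugin():
    """G = 3 kPa, gamma_hat = 1e15, Lambda = 0.014/min -> l_sigma = 113 um."""
    l = stress_propagation_length(3.0e3, 1.0e15, per_min_to_per_s(0.014))
    assert np.isclose(m_to_um(l), 113.4, rtol=1e-3)


def test_stress_propagation_length_scaling():
    base = stress_propagation_length(1.0, 1.0, 1.0)
    assert np.isclose(stress_propagation_length(4.0, 1.0, 1.0), 2.0 * base)
    assert np.isclose(stress_propagation_length(1.0, 4.0, 1.0), 0.5 * base)


def test_stress_profile_shape_and_curvature():
    p = MaterialParams(P0=10.0)
    y0 = um_to_m(30.0)
    y = np.linspace(0.0, y0, 11)
    s = stress_profile_1d(p, y0, y)
    # compressive everywhere, most negative at the centre, -P0 at the edge
    assert np.all(s <= -p.P0 + 1e-12)
    assert s[0] == s.min()
    assert np.isclose(s[-1], -p.P0)
    # quadratic: second finite difference equals gamma_hat * Lambda
    d2 = np.diff(s, 2) / np.diff(y)[0] ** 2
    assert np.allclose(d2, stress_profile_curvature(p), rtol=1e-9)
    with pytest.raises(ValueError):
        stress_profile_1d(p, y0, [-1.0])


def test_torque_closed_form():
    """gamma = 1, Lambda = 1, L = 2, theta = 45 deg: torque = L^3/24 = 1/3."""
    p = MaterialParams(gamma=1.0, Lambda=1.0, L=2.0)
    tau = torque_1d(p, np.pi / 4, y0=5.0)
    assert np.isclose(tau, 2.0**3 / 24.0, rtol=1e-10)
    # independent of the rod's height for a linear flow
    assert np.isclose(torque_1d(p, np.pi / 4, y0=-3.0), tau, rtol=1e-10)


@pytest.mark.parametrize("seed", range(10))
def test_torque_quadrature_matches_closed_form(seed):
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(0.1, 10.0)
    Lambda = rng.uniform(0.01, 1.0)
    L = rng.uniform(0.5, 5.0)
    theta = rng.uniform(0.0, np.pi)
    p = MaterialParams(gamma=gamma, Lambda=Lambda, L=L)
    tau = torque_1d(p, theta, y0=rng.uniform(-5, 5))
    expected = gamma * Lambda * L**3 * np.sin(2.0 * theta) / 24.0
    assert np.isclose(tau, expected, rtol=1e-8, atol=1e-12)


def test_alignment_rate_1d_value_and_stability():
    """gamma = 1, L = 2, zeta = 1, dv/dy = 1, theta = 45 deg -> rate 8/24."""
    p = MaterialParams(gamma=1.0, L=2.0, zeta=1.0)
    assert np.isclose(alignment_rate_1d(p, np.pi / 4, 1.0), 8.0 / 24.0)
    # extensional flow: theta = 90 deg stable, theta = 0 unstable
    eps = 1e-3
    assert alignment_rate_1d(p, np.pi / 2 - eps, 1.0) > 0  # pushed towards pi/2
    assert alignment_rate_1d(p, 0.0 + eps, 1.0) > 0  # pushed away from 0


def test_alignment_rate_2d_value_and_uniform_growth():
    prof = RadialGrowthProfile(g=lambda r: 0.1 * r, gprime=lambda r: 0.1)
    rate = alignment_rate_2d(0.7, prof, r=1.0, S=0.5, theta=np.pi / 4, phi=0.0)
    assert np.isclose(rate, 0.7 * 0.1 * 1.0 / (4 * 0.5) * 1.0)
    uni = RadialGrowthProfile.uniform(0.014)
    for th in np.linspace(0, np.pi, 7):
        assert alignment_rate_2d(0.7, uni, 3.0, 0.7, th, 1.0) == 0.0
    with pytest.raises(ValueError):
        alignment_rate_2d(0.7, prof, 1.0, 0.0, 0.1, 0.0)


def test_bulk_order_fixed_point():
    # standard choice: rho = rho0, rho_c = rho0/2, beta = alpha0 rho0/2
    s = bulk_order_fixed_point(alpha0=0.01, rho=1.0, rho_c=0.5, beta=0.005)
    assert np.isclose(2.0 * s**2, 1.0)
    # below the critical density the isotropic state is the fixed point
    assert bulk_order_fixed_point(0.01, 0.3, 0.5, 0.005) == 0.0


def test_screening_and_control_parameter():
    assert np.isclose(screening_length(4.0, 1.0), 2.0)
    assert np.isclose(turbulence_control_parameter(0.02, 1.0, 1.0, 0.01), 2.0)
    with pytest.raises(ValueError):
        turbulence_control_parameter(0.02, 1.0, 0.0, 0.01)


def test_active_length_estimates_labels():
    from activecolony.theory import active_length_estimates

    out = active_length_estimates(K=4.0, a=1.0, L=4e-6)
    assert np.isclose(out["wet_balance"], 2.0)
    assert out["cell_scale"] == 4e-6
    assert np.isnan(out["dry_relaxational"])
    full = active_length_estimates(Khat=0.01, alpha0=0.01, a0=0.02, gamma_hat=1.0, rho=1.0)
    assert np.isclose(full["dry_relaxational"], 1.0 / np.sqrt(2.0))
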