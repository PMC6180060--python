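import numpy as np
import pytest

from activecolony.continuum import (
    FieldState,
    SimParams,
    boundary_psi,
    colony_radius,
    hubble_constant,
    initial_state,
    low_order_fraction,
    run_simulation,
    solve_velocity,
    step_density,
    step_qtensor,
)


def _small(**kw):
    return SimParams(n=64, **kw)


def test_params_validation():
    with pytest.raises(ValueError):
        SimParams(Lambda=-1.0)
    with pytest.raises(ValueError):
        SimParams(a0=-0.01)
    with pytest.raises(ValueError):
        SimParams(Khat=10.0, dt=0.1)  # violates Q-diffusion bound
    with pytest.raises(ValueError):
        SimParams(G=100.0, dt=0.1)  # violates pressure-diffusion bound
    p = SimParams()
    assert p.beta == p.alpha0 * p.rho0 / 2.0
    assert p.rho_c == p.rho0 / 2.0


def test_initial_state_geometry():
    p = _small()
    st = initial_state(p)
    assert np.isclose(colony_radius(st, p), p.init_radius, rtol=0.1)
    outside = st.rho == 0.0
    assert np.all(st.Qxx[outside] == 0.0)
    assert np.abs(st.Qxx).max() <= p.noise


def test_mass_balance_matches_growth_rate():
    """Closed box: d/dt of total mass equals Lambda * mass exactly."""
    p = _small(noise=0.0)
    snaps = run_simulation(p, t_end=50.0, snapshot_every=50.0)
    m0 = snaps[0].rho.sum()
    m1 = snaps[-1].rho.sum()
    t = snaps[-1].time
    rate = np.log(m1 / m0) / t
    # discrete-time exact rate is log(1 + Lambda dt)/dt
    expected = np.log1p(p.Lambda * p.dt) / p.dt
    assert np.isclose(rate, expected, rtol=1e-6)


def test_homogeneous_bulk_reaches_fixed_point():
    """With rho = rho0 everywhere and aligned Q, 2 S^2 relaxes to alpha/beta = 1."""
    p = _small(a0=0.0, noise=0.0)
    n = p.n
    rho = np.full((n, n), p.rho0)
    st = FieldState(
        rho=rho,
        Qxx=np.full((n, n), 0.1),
        Qxy=np.zeros((n, n)),
        vx=np.zeros((n, n)),
        vy=np.zeros((n, n)),
        time=0.0,
        dx=p.dx,
    )
    for _ in range(40000):
        st.Qxx, st.Qxy = step_qtensor(st, p, p.dt)
    s2 = 2.0 * st.S**2
    assert np.allclose(s2, 1.0, atol=1e-6)


def test_velocity_zero_in_vacuum_and_dilute_regions():
    p = _small()
    st = initial_state(p)
    vx, vy = solve_velocity(st, p)
    dilute = st.rho < p.v_threshold
    assert np.all(vx[dilute] == 0.0)
    assert np.all(vy[dilute] == 0.0)


def test_density_stays_nonnegative_and_grows():
    p = _small()
    st = initial_state(p)
    for _ in range(200):
        st.vx, st.vy = solve_velocity(st, p)
        st.rho = step_density(st, p, p.dt)
        st.time += p.dt
    assert st.rho.min() >= 0.0
    assert st.rho.sum() > initial_state(p).rho.sum()


def test_deterministic_given_seed():
    p = _small(seed=3)
    s1 = run_simulation(p, t_end=20.0)[-1]
    s2 = run_simulation(p, t_end=20.0)[-1]
    assert np.array_equal(s1.rho, s2.rho)
    assert np.array_equal(s1.Qxx, s2.Qxx)


def test_expansion_is_subballistic_hubble():
    """The measured expansion slope is positive and below the growth rate."""
    p = SimParams(n=96)
    snaps = run_simulation(p, t_end=1200.0, snapshot_every=1200.0)
    st = snaps[-1]
    st.vx, st.vy = solve_velocity(st, p)
    fit = hubble_constant(st, p)
    assert 0.0 < fit.H < p.Lambda


def test_boundary_psi_values_in_range():
    p = SimParams(n=96)
    st = run_simulation(p, t_end=800.0)[-1]
    psi = boundary_psi(st, p)
    assert psi.size > 0
    assert np.all((psi >= 0.0) & (psi <= 90.0))


def test_low_order_fraction_of_aligned_disc_is_zero():
    p = _small(noise=0.0)
    st = initial_state(p)
    st.Qxx = np.where(st.rho > 0, 1.0 / np.sqrt(2.0), 0.0)
    frac, dens = low_order_fraction(st, p)
    assert frac == 0.0
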