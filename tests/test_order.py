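import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from activecolony.order import (
    aspect_ratio,
    boundary_anchoring,
    boundary_loop,
    correlation_functions,
    correlation_length,
    correlation_lengths,
    expansion_rate,
    global_order,
    global_order_pairsum,
    growth_rate_profile,
    hubble_fit,
    inscribed_radius,
    radial_velocity_profile,
    track_cells,
)
from activecolony.synth import make_aligned_colony, two_cell_pair
from activecolony.types import ColonyFrame, ColonyTimeSeries


def test_global_order_aligned_is_unity():
    fr = make_aligned_colony(16, angle=1.1)
    assert np.isclose(global_order(fr), 1.0)


def test_global_order_two_perpendicular_cells_is_zero():
    assert np.isclose(global_order(np.array([0.0, np.pi / 2])), 0.0, atol=1e-12)


def test_global_order_random_scales_as_inverse_sqrt_n():
    n = 10_000
    vals = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        vals.append(global_order(rng.uniform(0, np.pi, n)))
    rms = np.sqrt(np.mean(np.square(vals)))
    assert np.isclose(rms, 1.0 / np.sqrt(n), rtol=0.2)


@given(st.lists(st.floats(0, np.pi), min_size=2, max_size=40))
@settings(max_examples=50, deadline=None)
def test_pairsum_equals_mean_tensor_form(angles):
    a = np.asarray(angles)
    assert np.isclose(global_order(a), global_order_pairsum(a), atol=1e-10)


# -- correlation functions ----------------------------------------------------


def _single(length=2.0, width=1.0):
    return ColonyFrame(
        time=0.0,
        ids=np.array([0]),
        x=np.array([0.0]),
        y=np.array([0.0]),
        length=np.array([length]),
        width=np.array([width]),
        angle=np.array([0.0]),
    )


def test_single_cell_calibration_exact():
    cur = correlation_functions(_single(), r_max=5.0, dr=0.05)
    lp, lq = correlation_lengths(cur)
    assert np.isclose(lp, 1.0, atol=1e-9)
    assert np.isclose(lq, 0.5, atol=1e-9)


def test_two_cell_configurations():
    sbs = two_cell_pair(length=2.0, width=1.0, arrangement="side_by_side", gap=0.0)
    lp, _ = correlation_lengths(correlation_functions(sbs, r_max=6.0, dr=0.05))
    assert np.isclose(lp, 1.0, atol=1e-9)
    eo = two_cell_pair(length=2.0, width=1.0, arrangement="end_on", gap=0.0)
    _, lq = correlation_lengths(correlation_functions(eo, r_max=6.0, dr=0.05))
    assert np.isclose(lq, 0.5, atol=1e-9)


def test_correlation_length_closed_forms():
    r = np.linspace(0, 60.0, 24001)
    lam = 2.0
    assert np.isclose(correlation_length(r, np.exp(-r / lam)), lam, rtol=1e-3)
    L = 3.0
    tri = np.clip(1 - r / L, 0, None)
    assert np.isclose(correlation_length(r, tri), L / 2, rtol=1e-3)


# -- colony shape and anchoring ------------------------------------------------


def test_aspect_ratio_of_a_file_of_cells():
    fr = make_aligned_colony(8, angle=0.0, length=3.0, width=0.9, gap=0.1)
    res = aspect_ratio(fr)
    assert res.aspect_ratio > 3.0
    assert res.long_axis > res.short_axis


def test_boundary_anchoring_tangential_on_colony(medium_colony):
    res = boundary_anchoring(medium_colony[-1])
    assert 0 <= res.median_psi <= 90
    assert res.hist_counts.sum() == len(res.psi_deg)
    # growing colonies anchor tangentially: median well below 45 deg
    assert res.median_psi < 45


def test_boundary_loop_encloses_colony(medium_colony):
    fr = medium_colony[-1]
    idx = boundary_loop(fr)
    assert len(idx) >= 3
    r_in = inscribed_radius(fr)
    assert r_in > 0


# -- tracking and expansion -----------------------------------------------------


def _translating_series(v=(0.1, -0.05), n=9, dt=2.0):
    base = make_aligned_colony(n, angle=0.3)
    frames = []
    for k in range(3):
        frames.append(
            ColonyFrame(
                time=k * dt,
                ids=base.ids.copy(),
                x=base.x + v[0] * k * dt,
                y=base.y + v[1] * k * dt,
                length=base.length.copy(),
                width=base.width.copy(),
                angle=base.angle.copy(),
            )
        )
    return ColonyTimeSeries(frames=frames)


def test_track_cells_recovers_uniform_velocity():
    s = _translating_series()
    tr = track_cells(s)
    moving = tr[tr.frame > 0]
    assert np.allclose(moving.vx, 0.1, atol=1e-9)
    assert np.allclose(moving.vy, -0.05, atol=1e-9)
    # one track per cell
    assert tr.track_id.nunique() == s[0].n_cells


def test_hubble_fit_on_exact_linear_profile():
    # points symmetric within each bin, so the binned means sit exactly on H*r
    r = np.arange(0.25, 20.0, 0.5)
    H = 0.007
    fit = hubble_fit(r, H * r, bin_width=2.0)
    assert np.isclose(fit.H, H, rtol=1e-9)
    assert abs(fit.intercept) < 1e-12


def test_expansion_rate_on_agent_colony(medium_colony):
    H = expansion_rate(medium_colony)
    assert 0.3 * 0.014 < H < 0.6 * 0.014


def test_radial_velocity_requires_predecessor(medium_colony):
    with pytest.raises(ValueError):
        radial_velocity_profile(medium_colony, 0)


def test_growth_rate_profile_flat_and_correct(medium_colony):
    gp = growth_rate_profile(medium_colony)
    assert np.isclose(gp.Lambda_hat, 0.014, rtol=0.10)
    assert gp.flatness() < 0.10
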