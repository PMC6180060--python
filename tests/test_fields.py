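import numpy as np
import pytest

from activecolony.fields import GrainParams, Grid, QTensorField, density_field, q_tensor_field, smear_cell
from activecolony.synth import make_aligned_colony, two_cell_pair
from activecolony.types import ColonyFrame, RodCell


def _single(length=3.0, width=1.0, angle=0.0):
    return ColonyFrame(
        time=0.0,
        ids=np.array([0]),
        x=np.array([0.0]),
        y=np.array([0.0]),
        length=np.array([length]),
        width=np.array([width]),
        angle=np.array([angle]),
    )


@pytest.mark.parametrize("sigma_factor", [0.5, 1.0, 2.0])
def test_smear_integral_equals_cell_area(sigma_factor):
    """The smeared footprint integrates to L*W for any smoothing length."""
    L, W = 3.0, 0.9
    cell = RodCell(id=0, x=0.0, y=0.0, length=L, width=W, angle=0.4)
    sigma = sigma_factor * W
    grid = Grid.centered(L + 8 * sigma, 512)
    f = smear_cell(cell, grid, GrainParams(sigma=sigma))
    assert np.isclose(f.integral(), L * W, rtol=2e-3)


def test_smear_centroid_value():
    """At the cell centre f = tanh(L/2 sigma) * tanh(W/2 sigma)."""
    L, W, sigma = 4.0, 0.9, 0.9
    cell = RodCell(id=0, x=0.0, y=0.0, length=L, width=W, angle=0.0)
    grid = Grid.centered(10.0, 401)  # odd count -> node exactly at origin
    f = smear_cell(cell, grid, GrainParams(sigma=sigma))
    centre = f.values[200, 200]
    assert np.isclose(centre, np.tanh(L / (2 * sigma)) * np.tanh(W / (2 * sigma)), atol=1e-12)


def test_density_is_sum_of_cells():
    fr = two_cell_pair(length=3.0, width=1.0, arrangement="side_by_side", gap=0.5)
    grid = Grid.for_frame(fr)
    rho = density_field(fr, grid)
    total = sum(fr.length * fr.width)
    assert np.isclose(rho.integral(), total, rtol=5e-3)


def test_q_director_matches_single_cell():
    fr = _single(angle=0.6)
    grid = Grid.for_frame(fr)
    qf = q_tensor_field(fr, grid)
    mask = qf.S > 0.5 * qf.S.max()
    assert np.allclose(qf.director_angle[mask], 0.6, atol=1e-9)


def test_perpendicular_cells_cancel():
    """Q contributions of perpendicular overlapping cells cancel: S -> 0."""
    fr = ColonyFrame(
        time=0.0,
        ids=np.array([0, 1]),
        x=np.zeros(2),
        y=np.zeros(2),
        length=np.full(2, 3.0),
        width=np.full(2, 3.0),
        angle=np.array([0.0, np.pi / 2]),
    )
    grid = Grid.centered(6.0, 121)
    qf = q_tensor_field(fr, grid)
    assert qf.S[60, 60] < 1e-12
    rho = density_field(fr, grid)
    assert rho.values[60, 60] > 1.5  # density does not cancel


def test_cell_outside_grid_raises():
    fr = _single()
    grid = Grid(x0=5.0, y0=5.0, h=0.3, nx=30, ny=30)
    with pytest.raises(ValueError):
        q_tensor_field(fr, grid)


def test_qfield_mask_and_interpolators():
    fr = make_aligned_colony(9, angle=0.0)
    grid = Grid.for_frame(fr)
    qf = q_tensor_field(fr, grid)
    assert qf.valid_mask.any()
    qxx, qxy = qf.interpolators()
    c = fr.centroid()
    v = qxx(c[0], c[1])
    assert np.isfinite(v)
    with pytest.raises(ValueError):
        qxx(grid.extent[1] + 10.0, 0.0)


def test_grid_geometry():
    g = Grid.centered(5.0, 11)
    assert g.h == 1.0
    assert g.shape == (11, 11)
    X, Y = g.meshgrid()
    assert X[0, 0] == -5.0 and Y[-1, -1] == 5.0
    with pytest.raises(ValueError):
        Grid(x0=0, y0=0, h=-1.0, nx=4, ny=4)
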