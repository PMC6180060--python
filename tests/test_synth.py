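import numpy as np
import pytest

from activecolony.defects import winding_number
from activecolony.fields import Grid
from activecolony.synth import (
    GrowthParams,
    MCParams,
    PackingError,
    PassiveMC,
    grow_colony,
    make_aligned_colony,
    make_defect_field,
    periodic_images,
    sample_passive_mc,
    two_cell_pair,
)


# -- agent-based grower ------------------------------------------------------


def test_single_cell_elongates_exponentially():
    p = GrowthParams(seed=0, L_div=100.0)  # threshold unreachable
    series = grow_colony(p, n_final=1, record_every=10.0, t_max=50.0)
    for fr in series:
        assert fr.n_cells == 1
        assert np.isclose(fr.length[0], p.L0 * np.exp(p.Lambda * fr.time), rtol=1e-9)


def test_total_area_grows_exponentially(small_colony):
    a0 = (small_colony[0].length * small_colony[0].width).sum()
    for fr in small_colony:
        expected = a0 * np.exp(0.014 * fr.time)
        assert np.isclose((fr.length * fr.width).sum(), expected, rtol=1e-9)


def test_growth_deterministic_given_seed():
    s1 = grow_colony(GrowthParams(seed=4), n_final=20)
    s2 = grow_colony(GrowthParams(seed=4), n_final=20)
    assert len(s1) == len(s2)
    assert np.array_equal(s1[-1].x, s2[-1].x)
    assert np.array_equal(s1[-1].angle, s2[-1].angle)


def test_division_recorded_in_lineage(small_colony):
    assert len(small_colony.lineage) >= small_colony[-1].n_cells - 1
    last = small_colony[-1]
    # cells stay shorter than ~ the largest plausible division threshold
    assert last.length.max() < 4.0 * np.exp(3 * 0.10) * 1.2


def test_growth_params_validation():
    with pytest.raises(ValueError):
        GrowthParams(Lambda=-1.0)
    with pytest.raises(ValueError):
        GrowthParams(L_div=1.0, width=0.9)


# -- deterministic micro-configurations --------------------------------------


def test_two_cell_pair_arrangements():
    sbs = two_cell_pair(length=2.0, width=1.0, arrangement="side_by_side", gap=0.1)
    eo = two_cell_pair(length=2.0, width=1.0, arrangement="end_on", gap=0.1)
    assert sbs.n_cells == eo.n_cells == 2
    # side-by-side: separated perpendicular to the axis; end-on: along it
    assert np.ptp(sbs.x) < 1e-12 and np.ptp(sbs.y) > 0
    assert np.ptp(eo.y) < 1e-12 and np.ptp(eo.x) > 0
    with pytest.raises(ValueError):
        two_cell_pair(arrangement="diagonal")


def test_make_aligned_colony_orientations():
    fr = make_aligned_colony(9, angle=0.7)
    assert np.allclose(fr.angle, 0.7)


# -- analytic defect fields ---------------------------------------------------


def test_defect_field_winding_matches_construction():
    grid = Grid.centered(12.0, 192)
    fld = make_defect_field([((-4.0, 0.0), 0.5, 0.3), ((4.0, 1.0), -0.5, 0.0)], grid)
    assert winding_number(fld, (-4.0, 0.0), 1.5) == 0.5
    assert winding_number(fld, (4.0, 1.0), 1.5) == -0.5
    # far from both defects the total winding is the sum of charges
    assert winding_number(fld, (0.0, 0.0), 9.0) == 0.0


def test_defect_field_rejects_bad_input():
    grid = Grid.centered(10.0, 64)
    with pytest.raises(ValueError):
        make_defect_field([((0.0, 0.0), 0.3, 0.0)], grid)  # not half-integer
    with pytest.raises(ValueError):
        make_defect_field(
            [((0.0, 0.0), 0.5, 0.0), ((0.1, 0.0), -0.5, 0.0)], grid
        )  # cores too close


def test_uniform_field_has_no_charge():
    from activecolony.defects import charge_density

    grid = Grid.centered(10.0, 64)
    fld = make_defect_field([], grid)
    assert np.allclose(charge_density(fld).values, 0.0)


# -- passive Monte Carlo ------------------------------------------------------


@pytest.fixture(scope="module")
def tiny_mc():
    return MCParams(n_particles=30, area_fraction=0.5, n_sweeps=40, n_equil=20, sample_every=20, seed=1)


def test_mc_preserves_hard_core(tiny_mc):
    mc = PassiveMC(tiny_mc)
    for _ in range(30):
        mc.sweep()
    assert not mc._any_overlap()


def test_mc_dilute_acceptance_near_unity():
    p = MCParams(n_particles=2, box=60.0, n_sweeps=50, seed=0)
    mc = PassiveMC(p)
    for _ in range(50):
        mc.sweep()
    assert mc.acceptance_rate > 0.95


def test_mc_deterministic(tiny_mc):
    f1 = sample_passive_mc(tiny_mc)
    f2 = sample_passive_mc(tiny_mc)
    assert np.array_equal(f1[-1].x, f2[-1].x)


def test_mc_overpacked_raises():
    with pytest.raises(PackingError):
        PassiveMC(MCParams(n_particles=60, box=8.0, seed=0))


def test_isotropic_compression_reaches_density():
    p = MCParams(n_particles=40, area_fraction=0.55, init="isotropic", seed=2)
    mc = PassiveMC(p)
    assert np.isclose(mc.box, mc.target_box)
    assert not mc._any_overlap()


def test_periodic_images_pad():
    p = MCParams(n_particles=20, area_fraction=0.4, seed=5)
    mc = PassiveMC(p)
    fr = mc.frame(0.0)
    padded = periodic_images(fr, box=mc.box, margin=4.0)
    assert padded.n_cells > fr.n_cells
    assert np.array_equal(padded.x[: fr.n_cells], fr.x)
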