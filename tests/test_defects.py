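import numpy as np
import pytest

from activecolony.defects import (
    DefectObservation,
    charge_density,
    charge_statistics,
    detect_defects,
    isolated_defect_peak,
    link_defects,
    winding_number,
)
from activecolony.fields import Grid
from activecolony.synth import make_defect_field


def test_signed_charge_of_neutral_pair_vanishes(defect_pair_field):
    q = charge_density(defect_pair_field)
    total = q.integral()
    assert abs(total) < 0.02


def test_winding_numbers_around_cores(defect_pair_field):
    assert winding_number(defect_pair_field, (-6.0, 0.0), 1.5) == 0.5
    assert winding_number(defect_pair_field, (6.0, 0.0), 1.5) == -0.5


def test_winding_loop_off_grid_raises(defect_pair_field):
    with pytest.raises(ValueError):
        winding_number(defect_pair_field, (0.0, 0.0), 100.0)


def test_charge_density_integral_per_core():
    """The charge density integrated over a disc around a core equals m."""
    grid = Grid.centered(16.0, 384)
    fld = make_defect_field([((-5.0, 0.0), 0.5, 0.2), ((5.0, 0.0), -0.5, 0.0)], grid)
    q = charge_density(fld)
    X, Y = grid.meshgrid()
    h2 = grid.h**2
    disc_p = np.hypot(X + 5.0, Y) < 4.0
    disc_m = np.hypot(X - 5.0, Y) < 4.0
    assert np.isclose(q.values[disc_p].sum() * h2, 0.5, atol=0.02)
    assert np.isclose(q.values[disc_m].sum() * h2, -0.5, atol=0.02)


def test_detect_defects_positions_charges_polarity(defect_pair_field):
    dets = detect_defects(defect_pair_field)
    assert len(dets) == 2
    by_charge = {round(d.charge * 2): d for d in dets}
    plus, minus = by_charge[1], by_charge[-1]
    h = defect_pair_field.grid.h
    assert np.hypot(plus.x + 6.0, plus.y) < 3 * h
    assert np.hypot(minus.x - 6.0, minus.y) < 3 * h
    # +1/2 comet polarity for a phase-0 construction: the far -1/2 defect
    # shifts the local phase, but the vector is still a unit vector
    assert plus.polarity is not None and np.isclose(np.linalg.norm(plus.polarity), 1.0)
    assert minus.polarity is None


def test_isolated_plus_half_polarity_is_minus_x():
    """Isolated +1/2 with local phase 0 points its comet along -x."""
    grid = Grid.centered(12.0, 256)
    fld = make_defect_field([((0.0, 0.0), 0.5, 0.0)], grid)
    (det,) = detect_defects(fld)
    assert np.allclose(det.polarity, [-1.0, 0.0], atol=0.05)


def test_detect_no_false_positives_on_uniform_field():
    grid = Grid.centered(10.0, 128)
    fld = make_defect_field([], grid)
    assert detect_defects(fld) == []


def test_isolated_peak_calibration_monotone_in_resolution():
    p_coarse = isolated_defect_peak(0.3)
    p_fine = isolated_defect_peak(0.15)
    assert p_fine > p_coarse > 0


def test_defect_observation_validation():
    with pytest.raises(ValueError):
        DefectObservation(frame=0, x=0, y=0, charge=0.3, q_peak=1.0)
    with pytest.raises(ValueError):
        DefectObservation(frame=0, x=0, y=0, charge=0.5, q_peak=1.0, polarity=(2.0, 0.0))


def test_link_defects_follows_moving_defect():
    dets = []
    for f in range(5):
        dets.append(DefectObservation(frame=f, x=0.5 * f, y=0.0, charge=0.5, q_peak=1.0))
        dets.append(DefectObservation(frame=f, x=-0.5 * f, y=4.0, charge=-0.5, q_peak=1.0))
    tracks = link_defects(dets, max_disp=1.0)
    assert len(tracks) == 2
    for tr in tracks:
        assert tr.birth_frame == 0 and tr.death_frame == 4
        assert len(tr.observations) == 5


def test_link_defects_does_not_mix_charges():
    dets = [
        DefectObservation(frame=0, x=0.0, y=0.0, charge=0.5, q_peak=1.0),
        DefectObservation(frame=1, x=0.1, y=0.0, charge=-0.5, q_peak=1.0),
    ]
    tracks = link_defects(dets, max_disp=1.0)
    assert len(tracks) == 2


def test_charge_statistics_on_pair(defect_pair_field):
    dets = detect_defects(defect_pair_field)
    stats = charge_statistics(defect_pair_field, dets, centroid=(0.0, 0.0))
    assert abs(stats.total_signed) < 0.02
    assert stats.total_unsigned > 0.9  # ~|1/2| + |-1/2|
    assert stats.n_plus == 1 and stats.n_minus == 1
    assert np.isfinite(stats.r_moment_plus) and np.isfinite(stats.r_moment_minus)
    assert stats.polarity_alignment.shape == (1,)
    assert -1.0 <= stats.polarity_alignment[0] <= 1.0
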