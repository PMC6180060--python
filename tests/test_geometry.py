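import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from activecolony._geometry import (
    pair_overlaps,
    segment_closest_points,
    shaft_endpoints,
    spherocylinders_overlap,
)


def _brute_force_distance(a1, b1, a2, b2, n=400):
    t = np.linspace(0, 1, n)
    p = a1[None] + t[:, None] * (b1 - a1)[None]
    q = a2[None] + t[:, None] * (b2 - a2)[None]
    d = np.linalg.norm(p[:, None, :] - q[None, :, :], axis=-1)
    return d.min()


@given(st.lists(st.floats(-5, 5), min_size=8, max_size=8))
@settings(max_examples=60, deadline=None)
def test_segment_distance_matches_brute_force(coords):
    a1, b1 = np.array(coords[0:2]), np.array(coords[2:4])
    a2, b2 = np.array(coords[4:6]), np.array(coords[6:8])
    _, _, dist = segment_closest_points(a1[None], b1[None], a2[None], b2[None])
    expected = _brute_force_distance(a1, b1, a2, b2)
    assert dist[0] <= expected + 1e-9
    assert dist[0] >= expected - 0.05  # brute force grid resolution


def test_closest_points_realize_distance():
    rng = np.random.default_rng(0)
    pts = rng.uniform(-3, 3, size=(50, 8))
    a1, b1, a2, b2 = pts[:, 0:2], pts[:, 2:4], pts[:, 4:6], pts[:, 6:8]
    p1, p2, dist = segment_closest_points(a1, b1, a2, b2)
    assert np.allclose(np.linalg.norm(p1 - p2, axis=1), dist, atol=1e-12)


def test_shaft_endpoints_length():
    a, b = shaft_endpoints(1.0, 2.0, 0.3, 4.0, 1.0)
    assert np.isclose(np.linalg.norm(np.asarray(b) - np.asarray(a)), 3.0)
    # length below width: degenerate shaft at the centre
    a, b = shaft_endpoints(0.0, 0.0, 0.0, 0.8, 1.0)
    assert np.allclose(a, b)


def test_overlap_detection_known_cases():
    length = np.array([3.0, 3.0, 3.0, 3.0])
    width = np.ones(4)
    x = np.array([0.0, 0.0, 0.0, 0.0])
    y = np.array([0.0, 1.2, 0.8, 0.0])
    angle = np.array([0.0, 0.0, 0.0, np.pi / 2])
    pairs = np.array([[0, 1], [0, 2], [0, 3]])
    ov = spherocylinders_overlap(x, y, angle, length, width, pairs)
    # side-by-side with gap: no overlap; closer than width: overlap;
    # crossing perpendicular rods: overlap
    assert list(ov) == [False, True, True]


def test_pair_overlaps_depth_and_normal():
    x = np.array([0.0, 0.0])
    y = np.array([0.0, 0.7])
    angle = np.array([0.0, 0.0])
    length = np.array([3.0, 3.0])
    width = np.array([1.0, 1.0])
    pairs = np.array([[0, 1]])
    depth, normal, p1, p2 = pair_overlaps(x, y, angle, length, width, pairs)
    assert np.isclose(depth[0], 0.3)
    assert np.allclose(np.abs(normal[0]), [0.0, 1.0], atol=1e-12)
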