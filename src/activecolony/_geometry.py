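"""Spherocylinder geometry primitives.

A cell of pole-to-pole length ``L`` and diameter ``W`` is modelled as a 2D
spherocylinder: a line segment of length ``L - W`` (the shaft) dilated by a
disc of radius ``W/2``.  Two cells overlap when the distance between their
shafts is less than the sum of their radii.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def shaft_endpoints(x, y, angle, length, width):
    """Endpoints of the shaft segments of spherocylinders.

    Returns ``(a, b)`` arrays of shape ``(..., 2)``.  Degenerate cells with
    ``length <= width`` get zero-length shafts at the centroid.
    """
    half = 0.5 * np.maximum(np.asarray(length) - np.asarray(width), 0.0)
    ux, uy = np.cos(angle), np.sin(angle)
    c = np.stack([np.asarray(x, float), np.asarray(y, float)], axis=-1)
    d = np.stack([half * ux, half * uy], axis=-1)
    return c - d, c + d


def segment_closest_points(a1, b1, a2, b2):
    """Closest points between segment pairs ``a1-b1`` and ``a2-b2``.

    Vectorised form of the standard clamped closest-point algorithm
    (Ericson, *Real-Time Collision Detection*, §5.1.9).  Inputs are arrays
    of shape ``(n, 2)``; returns ``(p1, p2, dist)``.
    """
    a1 = np.atleast_2d(np.asarray(a1, float))
    b1 = np.atleast_2d(np.asarray(b1, float))
    a2 = np.atleast_2d(np.asarray(a2, float))
    b2 = np.atleast_2d(np.asarray(b2, float))

    d1 = b1 - a1
    d2 = b2 - a2
    r = a1 - a2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)

    denom = a * e - b * b
    s = np.where(denom > _EPS, np.clip((b * f - c * e) / np.where(denom > _EPS, denom, 1.0), 0.0, 1.0), 0.0)
    # t for the current s
    t = np.where(e > _EPS, (b * s + f) / np.where(e > _EPS, e, 1.0), 0.0)

    # re-clamp: if t was clamped (or segment 2 is degenerate), recompute s
    t_lo = (t < 0.0) | (e <= _EPS)
    t_hi = t > 1.0
    t = np.clip(t, 0.0, 1.0)
    safe_a = np.where(a > _EPS, a, 1.0)
    s = np.where(t_lo, np.clip(-c / safe_a, 0.0, 1.0), s)
    s = np.where(t_hi, np.clip((b - c) / safe_a, 0.0, 1.0), s)
    s = np.where(a > _EPS, s, 0.0)

    p1 = a1 + s[:, None] * d1
    p2 = a2 + t[:, None] * d2
    dist = np.linalg.norm(p1 - p2, axis=-1)
    return p1, p2, dist


def pair_overlaps(x, y, angle, length, width, pairs):
    """Penetration depths and contact geometry for candidate cell pairs.

    Parameters
    ----------
    pairs : (m, 2) int array of candidate index pairs.

    Returns
    -------
    depth : (m,) penetration depth (positive where cells overlap).
    normal : (m, 2) unit vector from cell ``j`` towards cell ``i``.
    p1, p2 : (m, 2) closest shaft points on cells ``i`` and ``j``.
    """
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    i, j = pairs[:, 0], pairs[:, 1]
    a, b = shaft_endpoints(x, y, angle, length, width)
    p1, p2, dist = segment_closest_points(a[i], b[i], a[j], b[j])
    depth = 0.5 * (np.asarray(width)[i] + np.asarray(width)[j]) - dist

    normal = p1 - p2
    # if shafts intersect, fall back to the centroid separation direction
    centre = np.stack([np.asarray(x, float), np.asarray(y, float)], axis=-1)
    fallback = centre[i] - centre[j]
    bad = dist < 1e-9
    normal = np.where(bad[:, None], fallback, normal)
    norms = np.linalg.norm(normal, axis=-1)
    norms = np.where(norms > _EPS, norms, 1.0)
    normal = normal / norms[:, None]
    return depth, normal, p1, p2


def spherocylinders_overlap(x, y, angle, length, width, pairs, tol=0.0):
    """Boolean overlap test for candidate pairs (``depth > tol``)."""
    depth, _, _, _ = pair_overlaps(x, y, angle, length, width, pairs)
    return depth > tol


def point_in_rectangles(px, py, x, y, angle, length, width):
    """Membership of a point in the sharp L x W rectangle of each cell.

    ``px, py`` scalars; cell arrays of shape (n,).  Returns boolean (n,).
    """
    dx = px - np.asarray(x, float)
    dy = py - np.asarray(y, float)
    ca, sa = np.cos(angle), np.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    return (np.abs(u) <= 0.5 * np.asarray(length)) & (np.abs(v) <= 0.5 * np.asarray(width))
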