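"""Colony-scale order, correlation, shape, anchoring and kinematics.

The statistics implemented here summarise a tracked colony frame by frame:

* global nematic order ``S(N)`` — 1 for perfect alignment, ``~1/sqrt(N)``
  for total disorder;
* director-frame two-point correlations of the Q field and the correlation
  lengths ``l_par``, ``l_perp`` obtained by integrating them;
* colony shape (second-moment-of-area axes), boundary anchoring angle
  ``psi`` against a closed spline through the outermost cells;
* cell tracking, the radial ("Hubble") expansion profile and the
  azimuthally averaged growth-rate profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree

from .types import ColonyFrame, ColonyTimeSeries

__all__ = [
    "CorrelationCurves",
    "HubbleFit",
    "AnchoringResult",
    "ShapeResult",
    "GrowthProfile",
    "global_order",
    "global_order_pairsum",
    "correlation_functions",
    "correlation_lengths",
    "correlation_length",
    "aspect_ratio",
    "boundary_anchoring",
    "boundary_loop",
    "inscribed_radius",
    "track_cells",
    "radial_velocity_profile",
    "expansion_rate",
    "hubble_fit",
    "growth_rate_profile",
]


# ---------------------------------------------------------------------------
# global order
# ---------------------------------------------------------------------------


def global_order(frame_or_angles) -> float:
    """Global nematic order ``S(N) = sqrt(<Qxx>^2 + <Qxy>^2)``.

    Computed from the colony-averaged per-cell order tensor; equals 1 when
    all cells are parallel and has r.m.s. value ``1/sqrt(N)`` for independent
    random orientations.  Axis-independent.
    """
    angles = _as_angles(frame_or_angles)
    if angles.size == 0:
        raise ValueError("global order of an empty colony is undefined")
    qxx = np.mean(np.cos(2 * angles))
    qxy = np.mean(np.sin(2 * angles))
    return float(np.hypot(qxx, qxy))


def global_order_pairsum(frame_or_angles) -> float:
    """Same statistic via the explicit pair sum ``(1/N) sqrt(sum_ij cos 2(ti - tj))``.

    Kept as an independent code path for cross-validation of
    :func:`global_order`.
    """
    angles = _as_angles(frame_or_angles)
    if angles.size == 0:
        raise ValueError("global order of an empty colony is undefined")
    diff = angles[:, None] - angles[None, :]
    total = np.sum(np.cos(2 * diff))
    return float(np.sqrt(max(total, 0.0)) / angles.size)


def _as_angles(frame_or_angles) -> np.ndarray:
    if isinstance(frame_or_angles, ColonyFrame):
        return frame_or_angles.angle
    return np.asarray(frame_or_angles, float).ravel()


# ---------------------------------------------------------------------------
# correlation functions
# ---------------------------------------------------------------------------


@dataclass
class CorrelationCurves:
    """Director-frame correlation curves sampled at bin midpoints.

    ``c0`` values are the zero-separation contractions used for
    normalisation in the correlation-length integrals.
    """

    r: np.ndarray  # bin midpoints (um)
    dr: float
    C_par: np.ndarray
    C_perp: np.ndarray
    c0_par: float
    c0_perp: float

    def lengths(self):
        """Correlation lengths ``l = int C dr / C(0)`` (midpoint rule)."""
        if self.c0_par <= 0 or self.c0_perp <= 0:
            raise ValueError("zero-separation correlation must be positive")
        l_par = float(np.sum(self.C_par) * self.dr / self.c0_par)
        l_perp = float(np.sum(self.C_perp) * self.dr / self.c0_perp)
        return l_par, l_perp


def correlation_functions(
    frame: ColonyFrame,
    r_max: float = 12.0,
    dr: float = 0.05,
    seed_mask=None,
) -> CorrelationCurves:
    """Two-point Q correlations along and across each cell's axis.

    For every seed cell ``i`` the sharp (top-hat) Q field of the frame is
    sampled along the rays ``r_i ± s nu_i`` (parallel) and
    ``r_i ± s nubar_i`` (perpendicular) and contracted with cell ``i``'s own
    unit tensor; the curve is the average over seed cells and ray signs:

    ``C(s) = < sum_{j owns point} 2 cos 2(theta_i - theta_j) >``.

    Calibration: a single isolated cell gives a top-hat curve, hence
    ``l_par = L/2`` and ``l_perp = W/2`` exactly.  ``seed_mask`` restricts
    the seed cells (e.g. to exclude periodic image cells) while all cells
    still contribute to the sampled field.
    """
    n = frame.n_cells
    if n == 0:
        raise ValueError("empty frame")
    seed_idx = np.arange(n) if seed_mask is None else np.flatnonzero(np.asarray(seed_mask))
    ns = seed_idx.size
    if ns == 0:
        raise ValueError("no seed cells selected")

    nbin = int(np.round(r_max / dr))
    s = (np.arange(nbin) + 0.5) * dr  # midpoints

    theta = frame.angle
    ca, sa = np.cos(theta), np.sin(theta)
    e_par = np.column_stack([ca, sa])[seed_idx]
    e_perp = np.column_stack([-sa, ca])[seed_idx]
    origin = frame.positions[seed_idx]

    # sample points: (ns seeds, 2 directions par/perp, 2 signs, nbin)
    pts = np.empty((ns, 2, 2, nbin, 2))
    for d, e in enumerate((e_par, e_perp)):
        for g, sgn in enumerate((1.0, -1.0)):
            pts[:, d, g, :, :] = origin[:, None, :] + sgn * s[None, :, None] * e[:, None, :]
    flat_pts = pts.reshape(-1, 2)
    seed_theta = np.broadcast_to(theta[seed_idx][:, None, None, None], (ns, 2, 2, nbin)).reshape(-1)

    accum = np.zeros(flat_pts.shape[0])
    # zero-separation values (seed centroids)
    accum0 = np.zeros(ns)

    tree = cKDTree(flat_pts)
    tree0 = cKDTree(origin)
    circum = 0.5 * np.hypot(frame.length, frame.width)
    for j in range(n):
        cj = (frame.x[j], frame.y[j])
        caj, saj = np.cos(frame.angle[j]), np.sin(frame.angle[j])
        for t, acc, th in ((tree, accum, seed_theta), (tree0, accum0, theta[seed_idx])):
            idx = t.query_ball_point(cj, circum[j])
            if not idx:
                continue
            idx = np.asarray(idx)
            p = (flat_pts if acc is accum else origin)[idx]
            dx = p[:, 0] - cj[0]
            dy = p[:, 1] - cj[1]
            u = dx * caj + dy * saj
            v = -dx * saj + dy * caj
            inside = (np.abs(u) <= 0.5 * frame.length[j]) & (np.abs(v) <= 0.5 * frame.width[j])
            if np.any(inside):
                sel = idx[inside]
                acc[sel] += 2.0 * np.cos(2.0 * (th[sel] - frame.angle[j]))

    A = accum.reshape(ns, 2, 2, nbin)
    C_par = A[:, 0].mean(axis=(0, 1))
    C_perp = A[:, 1].mean(axis=(0, 1))
    c0 = accum0.mean()
    return CorrelationCurves(r=s, dr=dr, C_par=C_par, C_perp=C_perp, c0_par=float(c0), c0_perp=float(c0))


def correlation_lengths(curves: CorrelationCurves):
    """Correlation lengths from :class:`CorrelationCurves` (midpoint quadrature)."""
    return curves.lengths()


def correlation_length(r, C) -> float:
    """Generic ``l = int_0^rmax C dr / C(0)`` by trapezoid for a sampled curve."""
    r = np.asarray(r, float)
    C = np.asarray(C, float)
    if C[0] <= 0:
        raise ValueError("C(0) must be positive")
    return float(np.trapezoid(C, r) / C[0])


# ---------------------------------------------------------------------------
# colony shape
# ---------------------------------------------------------------------------


@dataclass
class ShapeResult:
    long_axis: float
    short_axis: float
    aspect_ratio: float
    degenerate: bool


def aspect_ratio(frame: ColonyFrame) -> ShapeResult:
    """Colony axes from the second moment of the cell-mass distribution.

    Each cell contributes its footprint area at its centroid plus its own
    rectangle moment; the axes are the square roots of the two eigenvalues.
    A near-collinear colony is flagged degenerate.
    """
    if frame.n_cells < 2:
        raise ValueError("aspect ratio needs at least two cells")
    m = frame.cell_area
    com = frame.centroid()
    d = frame.positions - com
    I = np.einsum("i,ij,ik->jk", m, d, d)
    # own rectangle moments (per unit area), rotated into the lab frame
    c, s = np.cos(frame.angle), np.sin(frame.angle)
    iuu = frame.length**2 / 12.0
    ivv = frame.width**2 / 12.0
    I[0, 0] += np.sum(m * (iuu * c**2 + ivv * s**2))
    I[1, 1] += np.sum(m * (iuu * s**2 + ivv * c**2))
    I[0, 1] += np.sum(m * (iuu - ivv) * c * s)
    I[1, 0] = I[0, 1]
    I /= m.sum()
    ev = np.linalg.eigvalsh(I)
    short, long_ = np.sqrt(np.maximum(ev, 0.0))
    w = float(np.median(frame.width))
    degenerate = short < 0.75 * w
    ratio = float(long_ / short) if short > 0 else np.inf
    return ShapeResult(long_axis=float(long_), short_axis=float(short), aspect_ratio=ratio, degenerate=bool(degenerate))


# ---------------------------------------------------------------------------
# boundary anchoring
# ---------------------------------------------------------------------------


@dataclass
class AnchoringResult:
    boundary_indices: np.ndarray  # frame indices of boundary cells, loop order
    control_points: np.ndarray  # (k, 2) ordered boundary centroids
    psi_deg: np.ndarray  # acute tangent-director angle per boundary cell
    hist_counts: np.ndarray
    hist_edges: np.ndarray

    @property
    def median_psi(self) -> float:
        return float(np.median(self.psi_deg))


def _alpha_shape_loop(points: np.ndarray, alpha_radius: float):
    """Ordered boundary loop of the alpha shape of a point set.

    Keeps Delaunay triangles with circumradius below ``alpha_radius``; the
    edges used by exactly one kept triangle form the boundary.  Returns the
    longest closed loop of vertex indices, or ``None`` if the construction
    degenerates (e.g. cocircular points), in which case callers fall back to
    the convex hull.
    """
    try:
        tri = Delaunay(points)
    except Exception:
        return None
    p = points[tri.simplices]
    a = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    b = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
    c = np.linalg.norm(p[:, 2] - p[:, 0], axis=1)
    area2 = np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        circ = np.where(area2 > 1e-12, a * b * c / (2.0 * area2), np.inf)
    kept = tri.simplices[circ < alpha_radius]
    if kept.size == 0:
        return None
    edges: dict = {}
    for s in kept:
        for e in ((s[0], s[1]), (s[1], s[2]), (s[2], s[0])):
            key = (min(e), max(e))
            edges[key] = edges.get(key, 0) + 1
    boundary = [e for e, cnt in edges.items() if cnt == 1]
    if not boundary:
        return None
    adj: dict = {}
    for u, v in boundary:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    if any(len(vs) != 2 for vs in adj.values()):
        return None  # pinched boundary; caller falls back
    start = boundary[0][0]
    loop = [start]
    prev, cur = None, start
    while True:
        nxts = [v for v in adj[cur] if v != prev]
        if not nxts:
            return None
        prev, cur = cur, nxts[0]
        if cur == start:
            break
        loop.append(cur)
        if len(loop) > len(adj) + 1:
            return None
    if len(loop) < 3:
        return None
    return np.asarray(loop)


def boundary_loop(frame: ColonyFrame, alpha_factor: float = 2.0) -> np.ndarray:
    """Indices of the outermost cells, ordered around the colony.

    Uses a concave hull (alpha shape with radius ``alpha_factor`` times the
    median cell length); falls back to the convex hull when the alpha shape
    degenerates.
    """
    pts = frame.positions
    loop = _alpha_shape_loop(pts, alpha_factor * float(np.median(frame.length)))
    if loop is None:
        from scipy.spatial import ConvexHull

        try:
            hull = ConvexHull(pts)
        except Exception as exc:  # collinear colonies
            raise ValueError("cannot construct a colony boundary (degenerate geometry)") from exc
        loop = hull.vertices
    return loop


def boundary_anchoring(frame: ColonyFrame, alpha_factor: float = 2.0) -> AnchoringResult:
    """Anchoring angle ``psi`` between boundary cells and the boundary curve.

    A closed Catmull-Rom spline is threaded through the ordered centroids of
    the outermost cells; the tangent at control point ``k`` is
    ``(P_{k+1} - P_{k-1}) / 2`` and ``psi`` is the acute angle between that
    tangent and the cell axis.  Invariant under rigid rotations.
    """
    if frame.n_cells < 6:
        raise ValueError("boundary anchoring needs at least 6 cells")
    loop = boundary_loop(frame, alpha_factor)
    if loop.size < 3:
        raise ValueError("too few boundary cells")
    P = frame.positions[loop]
    T = np.roll(P, -1, axis=0) - np.roll(P, 1, axis=0)
    norms = np.linalg.norm(T, axis=1)
    good = norms > 1e-12
    T[good] /= norms[good, None]
    nu = frame.nu[loop]
    dot = np.abs(np.einsum("ij,ij->i", T, nu))
    psi = np.degrees(np.arccos(np.clip(dot, 0.0, 1.0)))
    counts, edges = np.histogram(psi, bins=np.arange(0.0, 91.0, 10.0))
    return AnchoringResult(
        boundary_indices=loop,
        control_points=P,
        psi_deg=psi,
        hist_counts=counts,
        hist_edges=edges,
    )


def inscribed_radius(frame: ColonyFrame, alpha_factor: float = 2.0) -> float:
    """Radius of the largest centroid-centred circle inside the boundary loop."""
    loop = boundary_loop(frame, alpha_factor)
    P = frame.positions[loop]
    c = frame.centroid()
    # min distance from centroid to the boundary polygon edges
    A = P
    B = np.roll(P, -1, axis=0)
    AB = B - A
    t = np.einsum("ij,ij->i", c - A, AB) / np.maximum(np.einsum("ij,ij->i", AB, AB), 1e-12)
    t = np.clip(t, 0.0, 1.0)
    proj = A + t[:, None] * AB
    return float(np.min(np.linalg.norm(proj - c, axis=1)))


# ---------------------------------------------------------------------------
# tracking and kinematics
# ---------------------------------------------------------------------------


def track_cells(
    series: ColonyTimeSeries,
    max_disp: float = 2.0,
    division_drop: float = 0.30,
) -> pd.DataFrame:
    """Frame-to-frame nearest-neighbour linking with division handling.

    Cells are matched greedily by centroid distance (closest pairs first,
    one-to-one, links beyond ``max_disp`` rejected).  A matched pair whose
    length drops by more than ``division_drop`` is treated as a division
    event: the link still propagates the track id but no velocity row is
    emitted across the event.  Ambiguous links (a target contested at nearly
    equal distance) are dropped for that interval.

    Returns a tidy table with one row per linked cell per frame interval:
    ``frame, time_min, track_id, x_um, y_um, vx, vy, length_um, angle_rad``.
    """
    rows = []
    if len(series) < 2:
        return pd.DataFrame(
            columns=["frame", "time_min", "track_id", "x_um", "y_um", "vx", "vy", "length_um", "angle_rad"]
        )
    track_of = {k: int(series[0].ids[k]) for k in range(series[0].n_cells)}
    next_track = int(series[0].ids.max()) + 1 if series[0].n_cells else 0

    for fidx in range(len(series) - 1):
        cur, nxt = series[fidx], series[fidx + 1]
        dt = nxt.time - cur.time
        if dt <= 0:
            raise ValueError("frame times must be strictly increasing")
        if cur.n_cells == 0 or nxt.n_cells == 0:
            track_of = {}
            continue
        tree = cKDTree(nxt.positions)
        dists, nn = tree.query(cur.positions, k=min(2, nxt.n_cells))
        dists = np.atleast_2d(dists)
        nn = np.atleast_2d(nn)
        if dists.shape[1] == 1:
            dists = np.column_stack([dists[:, 0], np.full(cur.n_cells, np.inf)])
            nn = np.column_stack([nn[:, 0], nn[:, 0]])
        order = np.argsort(dists[:, 0])
        claimed: set = set()
        new_track_of: dict = {}
        for i in order:
            d1 = dists[i, 0]
            if d1 > max_disp:
                continue
            target = int(nn[i, 0])
            ambiguous = dists[i, 1] - d1 < 0.25 * max(d1, 0.1)
            if target in claimed or ambiguous:
                continue  # flagged: dropped for this interval
            claimed.add(target)
            tid = track_of.get(i, None)
            if tid is None:
                tid = next_track
                next_track += 1
            new_track_of[target] = tid
            divided = nxt.length[target] < (1.0 - division_drop) * cur.length[i]
            if not divided:
                rows.append(
                    dict(
                        frame=fidx + 1,
                        time_min=nxt.time,
                        track_id=tid,
                        x_um=nxt.x[target],
                        y_um=nxt.y[target],
                        vx=(nxt.x[target] - cur.x[i]) / dt,
                        vy=(nxt.y[target] - cur.y[i]) / dt,
                        length_um=nxt.length[target],
                        angle_rad=nxt.angle[target],
                    )
                )
        # unmatched next-frame cells open new tracks
        for t in range(nxt.n_cells):
            if t not in new_track_of:
                new_track_of[t] = next_track
                next_track += 1
        track_of = new_track_of
    return pd.DataFrame(rows)


@dataclass
class HubbleFit:
    r_centers: np.ndarray
    vr_mean: np.ndarray
    counts: np.ndarray
    H: float  # slope, 1/min
    intercept: float
    r_fit_max: float


def hubble_fit(r, vr, bin_width: float = 2.0, r_fit_max: float | None = None) -> HubbleFit:
    """Azimuthally averaged radial-velocity profile and its linear fit."""
    r = np.asarray(r, float)
    vr = np.asarray(vr, float)
    if r_fit_max is None:
        r_fit_max = r.max()
    sel = r <= r_fit_max
    r, vr = r[sel], vr[sel]
    nb = max(int(np.ceil(r_fit_max / bin_width)), 1)
    edges = np.arange(nb + 1) * bin_width
    idx = np.clip(np.digitize(r, edges) - 1, 0, nb - 1)
    counts = np.bincount(idx, minlength=nb)
    sums = np.bincount(idx, weights=vr, minlength=nb)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    pop = counts > 0
    if pop.sum() < 3:
        raise ValueError("fewer than 3 populated radial bins")
    A = np.column_stack([centers[pop], np.ones(pop.sum())])
    coef, *_ = np.linalg.lstsq(A, means[pop], rcond=None)
    return HubbleFit(
        r_centers=centers,
        vr_mean=means,
        counts=counts,
        H=float(coef[0]),
        intercept=float(coef[1]),
        r_fit_max=float(r_fit_max),
    )


def radial_velocity_profile(
    series: ColonyTimeSeries,
    frame_index: int,
    bin_width: float = 2.0,
    fit_fraction: float = 0.9,
    tracks: pd.DataFrame | None = None,
) -> HubbleFit:
    """Hubble fit of the radial expansion velocity at one frame interval.

    Velocities come from nearest-neighbour tracking between frames
    ``frame_index - 1`` and ``frame_index``; the colony centre-of-mass motion
    is subtracted, and the fit is restricted to ``fit_fraction`` of the
    inscribed-circle radius to avoid edge bins.
    """
    if frame_index < 1 or frame_index >= len(series):
        raise ValueError("frame_index must address a frame with a predecessor")
    if tracks is None:
        sub = ColonyTimeSeries(frames=[series[frame_index - 1], series[frame_index]])
        tracks = track_cells(sub)
        tracks = tracks[tracks.frame == 1]
    else:
        tracks = tracks[tracks.frame == frame_index]
    if len(tracks) == 0:
        raise ValueError("no velocities available at this frame")
    cur, nxt = series[frame_index - 1], series[frame_index]
    dt = nxt.time - cur.time
    com0, com1 = cur.centroid(), nxt.centroid()
    vcom = (com1 - com0) / dt
    dx = tracks.x_um.to_numpy() - com1[0]
    dy = tracks.y_um.to_numpy() - com1[1]
    r = np.hypot(dx, dy)
    with np.errstate(invalid="ignore", divide="ignore"):
        rhatx = np.where(r > 1e-9, dx / np.maximum(r, 1e-9), 0.0)
        rhaty = np.where(r > 1e-9, dy / np.maximum(r, 1e-9), 0.0)
    vr = (tracks.vx.to_numpy() - vcom[0]) * rhatx + (tracks.vy.to_numpy() - vcom[1]) * rhaty
    try:
        R = inscribed_radius(nxt)
    except ValueError:
        R = r.max()
    return hubble_fit(r, vr, bin_width=bin_width, r_fit_max=fit_fraction * R)


def expansion_rate(series: ColonyTimeSeries, n_pairs: int = 6, bin_width: float = 2.0) -> float:
    """Mean Hubble slope over the last ``n_pairs`` frame intervals.

    Single-interval fits fluctuate because overdamped rearrangements are
    jerky (cells move only when pushed); averaging several intervals gives a
    stable expansion-rate estimate.
    """
    slopes = []
    for k in range(max(len(series) - n_pairs, 1), len(series)):
        try:
            slopes.append(radial_velocity_profile(series, k, bin_width=bin_width).H)
        except ValueError:
            continue
    if not slopes:
        raise ValueError("no frame interval yielded a radial-velocity fit")
    return float(np.mean(slopes))


@dataclass
class GrowthProfile:
    r_centers: np.ndarray
    rate_mean: np.ndarray  # 1/min
    counts: np.ndarray
    Lambda_hat: float

    def flatness(self, min_count: int = 3) -> float:
        """Max relative deviation of populated bins from the mean rate."""
        sel = self.counts >= min_count
        if not np.any(sel):
            raise ValueError("no populated bins")
        return float(np.max(np.abs(self.rate_mean[sel] - self.Lambda_hat)) / abs(self.Lambda_hat))


def growth_rate_profile(
    series: ColonyTimeSeries,
    window: int = 5,
    bin_width: float = 2.0,
    division_drop: float = 0.30,
) -> GrowthProfile:
    """Azimuthally averaged per-cell elongation rate versus radius.

    For every cell id, ``ln L(t)`` is regressed over sliding windows that
    exclude division events (length drops larger than ``division_drop``);
    each window yields a rate at the cell's mid-window position, binned by
    distance from the colony centroid of that frame.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    # collect per-id histories
    hist: dict = {}
    centroids = [f.centroid() for f in series]
    for fidx, f in enumerate(series):
        for k in range(f.n_cells):
            hist.setdefault(int(f.ids[k]), []).append(
                (f.time, f.length[k], f.x[k] - centroids[fidx][0], f.y[k] - centroids[fidx][1])
            )
    rates, radii = [], []
    for cid, recs in hist.items():
        if len(recs) < window:
            continue
        t = np.array([r[0] for r in recs])
        L = np.array([r[1] for r in recs])
        x = np.array([r[2] for r in recs])
        y = np.array([r[3] for r in recs])
        # split at division events within the id's own history
        breaks = np.flatnonzero(L[1:] < (1.0 - division_drop) * L[:-1]) + 1
        for seg in np.split(np.arange(len(recs)), breaks):
            if seg.size < window:
                continue
            for s0 in range(seg.size - window + 1):
                w = seg[s0 : s0 + window]
                slope = np.polyfit(t[w], np.log(L[w]), 1)[0]
                mid = w[window // 2]
                rates.append(slope)
                radii.append(np.hypot(x[mid], y[mid]))
    if not rates:
        raise ValueError("no division-free length history long enough for the window")
    rates = np.asarray(rates)
    radii = np.asarray(radii)
    nb = max(int(np.ceil(radii.max() / bin_width)), 1)
    edges = np.arange(nb + 1) * bin_width
    idx = np.clip(np.digitize(radii, edges) - 1, 0, nb - 1)
    counts = np.bincount(idx, minlength=nb)
    sums = np.bincount(idx, weights=rates, minlength=nb)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return GrowthProfile(
        r_centers=0.5 * (edges[:-1] + edges[1:]),
        rate_mean=means,
        counts=counts,
        Lambda_hat=float(rates.mean()),
    )
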