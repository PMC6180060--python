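"""Synthetic colony and control ensembles.

Three generators stand in for experimental data:

* :func:`grow_colony` — an agent-based model of a single-layer colony:
  spherocylindrical cells elongate exponentially at a spatially uniform rate
  ``Lambda``, divide symmetrically when they exceed a noisy threshold length,
  and push each other apart through hard-core repulsion relaxed by overdamped
  dynamics (drag proportional to cell length, mimicking frictional sliding on
  the substrate).
* :func:`sample_passive_mc` — equilibrium Metropolis Monte Carlo of *passive*
  (non-growing) hard spherocylinders with colony-like length and width
  distributions, the control that isolates the effect of growth activity.
* :func:`make_defect_field` — analytic director fields with prescribed
  topological charges, used as exact oracles for the defect machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from ._geometry import pair_overlaps, segment_closest_points, shaft_endpoints
from .types import ColonyFrame, ColonyTimeSeries, fold_angle

__all__ = [
    "GrowthParams",
    "MCParams",
    "OverlapRelaxationError",
    "PackingError",
    "grow_colony",
    "sample_passive_mc",
    "PassiveMC",
    "make_defect_field",
    "make_aligned_colony",
    "two_cell_pair",
    "periodic_images",
]


class OverlapRelaxationError(RuntimeError):
    """Hard-core overlap relaxation failed to converge."""


class PackingError(RuntimeError):
    """Requested particle density could not be realised."""


@dataclass
class GrowthParams:
    """Parameters of the agent-based colony generator.

    ``Lambda`` is the single-cell elongation rate (dL/dt = Lambda * L) in
    1/min; cells divide near ``L_div`` (um) into two halves.  ``div_noise``
    is the relative (lognormal) spread of the division length, which
    desynchronises divisions.  ``stiffness`` and ``friction`` set the
    hard-core repulsion spring and the per-length substrate drag; only their
    ratio matters for the quasi-static relaxation.  ``dt`` (min) is chosen so
    the elongation increment per step stays well below a cell width.
    """

    Lambda: float = 0.014  # 1/min
    L_div: float = 4.0  # um
    div_noise: float = 0.10
    width: float = 0.9  # um
    L0: float = 2.0  # um, initial cell length
    kick_sd_deg: float = 2.0
    stiffness: float = 25.0
    friction: float = 1.0
    dt: float = 0.5  # min
    seed: int = 0
    relax_tol: float = 0.05  # residual overlap tolerance, fraction of width
    max_relax_iter: int = 400
    lambda_of_t: Callable[[float], float] | None = None  # optional Lambda(t) hook

    def __post_init__(self):
        if self.Lambda <= 0 and self.lambda_of_t is None:
            raise ValueError("Lambda must be positive")
        if self.L_div <= 2 * self.width:
            raise ValueError("L_div must exceed twice the cell width")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def rate(self, t: float) -> float:
        return self.Lambda if self.lambda_of_t is None else float(self.lambda_of_t(t))


def _relax_overlaps(x, y, angle, length, width, params: GrowthParams):
    """Quasi-static removal of hard-core overlaps (overdamped spring forces).

    Force is linear in the shaft-shaft penetration depth and acts along the
    contact normal at the closest points; translational drag scales with cell
    length and rotational drag with length cubed.
    """
    n = x.size
    if n < 2:
        return 0.0
    tol = params.relax_tol * width.min()
    mobility = 1.0 / (params.friction * length)
    # pseudo-time chosen so a single contact relaxes a fixed fraction per sweep
    dtau = 0.4 * params.friction * length.min() / params.stiffness
    reach = length.max() + width.max()
    max_depth = 0.0
    for _ in range(params.max_relax_iter):
        tree = cKDTree(np.column_stack([x, y]))
        pairs = tree.query_pairs(reach, output_type="ndarray")
        if pairs.size == 0:
            return 0.0
        depth, normal, p1, p2 = pair_overlaps(x, y, angle, length, width, pairs)
        active = depth > 0
        if not np.any(active):
            return 0.0
        max_depth = depth[active].max()
        if max_depth < tol:
            return max_depth
        i = pairs[active, 0]
        j = pairs[active, 1]
        f = (params.stiffness * depth[active])[:, None] * normal[active]
        fx = np.zeros(n)
        fy = np.zeros(n)
        np.add.at(fx, i, f[:, 0])
        np.add.at(fy, i, f[:, 1])
        np.add.at(fx, j, -f[:, 0])
        np.add.at(fy, j, -f[:, 1])
        # torque about each centroid from the contact-point lever arm
        tq = np.zeros(n)
        ri = p1[active] - np.column_stack([x[i], y[i]])
        rj = p2[active] - np.column_stack([x[j], y[j]])
        np.add.at(tq, i, ri[:, 0] * f[:, 1] - ri[:, 1] * f[:, 0])
        np.add.at(tq, j, -(rj[:, 0] * f[:, 1] - rj[:, 1] * f[:, 0]))

        x += fx * mobility * dtau
        y += fy * mobility * dtau
        dtheta = tq * (12.0 * mobility / length**2) * dtau
        np.clip(dtheta, -0.1, 0.1, out=dtheta)
        angle += dtheta
    raise OverlapRelaxationError(
        f"residual overlap {max_depth:.3g} um above tolerance {tol:.3g} um "
        f"after {params.max_relax_iter} iterations"
    )


def grow_colony(
    params: GrowthParams,
    n_final: int,
    record_every: float = 5.0,
    t_max: float | None = None,
) -> ColonyTimeSeries:
    """Grow a colony from a single cell until it holds ``n_final`` cells.

    Each cell elongates as ``dL/dt = Lambda L`` (spatially uniform by
    construction) and splits symmetrically into two collinear halves of
    length ``L/2`` when it exceeds its division threshold, sampled per cell
    from a lognormal around ``L_div``.  Children receive a small angular kick
    (s.d. ``kick_sd_deg``).  After every step, hard-core overlaps created by
    elongation and division are relaxed quasi-statically.

    Returns a :class:`ColonyTimeSeries` with frames every ``record_every``
    minutes plus the final frame.  Deterministic for a given seed.
    """
    if n_final < 1:
        raise ValueError("n_final must be >= 1")
    rng = np.random.default_rng(params.seed)

    x = np.array([0.0])
    y = np.array([0.0])
    angle = np.array([0.0])
    length = np.array([params.L0])
    width = np.array([params.width])
    ids = np.array([0], dtype=np.int64)
    parent = np.array([-1], dtype=np.int64)
    thresh = np.array([params.L_div * rng.lognormal(0.0, params.div_noise)])
    next_id = 1
    lineage: dict[int, int] = {}

    t = 0.0
    if t_max is None:
        # generous bound: exponential growth reaches n_final well before this
        t_max = 3.0 * np.log(max(n_final, 2)) / params.Lambda + 10.0

    frames = [ColonyFrame(0.0, ids.copy(), x.copy(), y.copy(), length.copy(), width.copy(), angle.copy(), parent.copy())]
    next_record = record_every

    while ids.size < n_final and t < t_max:
        rate = params.rate(t)
        t += params.dt
        length = length * np.exp(rate * params.dt)

        dividing = np.flatnonzero(length > thresh)
        if dividing.size:
            keep = np.setdiff1d(np.arange(ids.size), dividing)
            new = {k: [] for k in ("x", "y", "angle", "length", "width", "ids", "parent", "thresh")}
            for k in dividing:
                off = 0.25 * length[k]
                ux, uy = np.cos(angle[k]), np.sin(angle[k])
                for sgn in (-1.0, 1.0):
                    kick = np.deg2rad(params.kick_sd_deg) * rng.standard_normal()
                    new["x"].append(x[k] + sgn * off * ux)
                    new["y"].append(y[k] + sgn * off * uy)
                    new["angle"].append(angle[k] + kick)
                    new["length"].append(0.5 * length[k])
                    new["width"].append(width[k])
                    new["ids"].append(next_id)
                    new["parent"].append(ids[k])
                    new["thresh"].append(params.L_div * rng.lognormal(0.0, params.div_noise))
                    lineage[next_id] = int(ids[k])
                    next_id += 1
            x = np.concatenate([x[keep], new["x"]])
            y = np.concatenate([y[keep], new["y"]])
            angle = np.concatenate([angle[keep], new["angle"]])
            length = np.concatenate([length[keep], new["length"]])
            width = np.concatenate([width[keep], new["width"]])
            ids = np.concatenate([ids[keep], np.array(new["ids"], dtype=np.int64)])
            parent = np.concatenate([parent[keep], np.array(new["parent"], dtype=np.int64)])
            thresh = np.concatenate([thresh[keep], new["thresh"]])

        _relax_overlaps(x, y, angle, length, width, params)
        angle = fold_angle(angle)

        if t >= next_record - 1e-9 or ids.size >= n_final:
            frames.append(
                ColonyFrame(t, ids.copy(), x.copy(), y.copy(), length.copy(), width.copy(), angle.copy(), parent.copy())
            )
            next_record = t + record_every

    return ColonyTimeSeries(frames=frames, lineage=lineage)


# ---------------------------------------------------------------------------
# passive hard-spherocylinder Monte Carlo
# ---------------------------------------------------------------------------


@dataclass
class MCParams:
    """Passive hard-spherocylinder Monte Carlo parameters.

    Particles live in a periodic square box with lengths drawn uniformly from
    ``length_range`` (the post-division to pre-division span of colony cells)
    and fixed width.  The box side defaults to the value giving the
    colony-like area fraction ``area_fraction`` (colonies are close-packed;
    their measured fraction is ~0.8-0.9); pass ``box`` to override.  Moves
    are single-particle translations/rotations accepted only if hard-core
    overlap free.
    """

    n_particles: int = 150
    box: float | None = None
    area_fraction: float = 0.8
    init: str = "aligned"  # "aligned" dense packing or "isotropic" compression
    length_range: tuple = (2.0, 4.0)
    width: float = 0.9
    n_sweeps: int = 2000
    n_equil: int = 500
    sample_every: int = 500
    max_trans: float = 0.15  # um
    max_rot: float = 0.15  # rad
    seed: int = 0
    max_insert_attempts: int = 200000


class PassiveMC:
    """Metropolis sampler for passive hard spherocylinders (periodic box)."""

    def __init__(self, params: MCParams):
        self.params = params
        self.rng = np.random.default_rng(params.seed)
        self.accepted = 0
        self.attempted = 0
        self._insert_initial()

    # -- geometry -----------------------------------------------------------
    def _min_image(self, dx):
        return dx - self.box * np.round(dx / self.box)

    def _overlaps_any(self, k, xk, yk, ak, exclude_self=True):
        """Does particle ``k`` at trial pose (xk, yk, ak) overlap any other?"""
        p = self.params
        dx = self._min_image(self.x - xk)
        dy = self._min_image(self.y - yk)
        cand = np.flatnonzero(dx * dx + dy * dy < (0.5 * (self.length + self.length[k]) + p.width) ** 2)
        if exclude_self:
            cand = cand[cand != k]
        if cand.size == 0:
            return False
        # trial particle at origin of the minimum-image frame
        a1, b1 = shaft_endpoints(0.0, 0.0, ak, self.length[k], p.width)
        a2, b2 = shaft_endpoints(dx[cand], dy[cand], self.angle[cand], self.length[cand], p.width)
        _, _, dist = segment_closest_points(
            np.broadcast_to(a1, (cand.size, 2)), np.broadcast_to(b1, (cand.size, 2)), a2, b2
        )
        return bool(np.any(dist < p.width - 1e-12))

    # -- setup --------------------------------------------------------------
    def _insert_initial(self):
        """Construct an overlap-free start at the requested density.

        ``init="aligned"`` (default) builds a dense packed configuration —
        rows of parallel rods, the constructible dense packing at colony-like
        area fractions, which at these densities is also the orientationally
        ordered branch the dense hard-rod system equilibrates on.
        ``init="isotropic"`` places particles by random sequential insertion
        in an inflated box (area fraction <= 0.3) and compresses to the
        target density; this quenches into an isotropic jammed glass.
        """
        p = self.params
        self.length = self.rng.uniform(*p.length_range, size=p.n_particles)
        shaft = np.maximum(self.length - p.width, 0.0)
        area = (shaft * p.width + 0.25 * np.pi * p.width**2).sum()
        self.target_box = p.box if p.box is not None else float(np.sqrt(area / p.area_fraction))
        if p.init == "aligned":
            self.box = self.target_box
            self._insert_aligned()
            return
        if p.init != "isotropic":
            raise ValueError("init must be 'aligned' or 'isotropic'")
        self.box = max(self.target_box, float(np.sqrt(area / 0.30)))
        self.x = np.empty(p.n_particles)
        self.y = np.empty(p.n_particles)
        self.angle = np.empty(p.n_particles)
        placed = 0
        attempts = 0
        while placed < p.n_particles:
            if attempts > p.max_insert_attempts:
                raise PackingError(
                    f"could not place {p.n_particles} particles in box {p.box} "
                    f"(area fraction too high for random insertion)"
                )
            attempts += 1
            xk = self.rng.uniform(0, self.box)
            yk = self.rng.uniform(0, self.box)
            ak = self.rng.uniform(0, np.pi)
            k = placed
            self.x[k], self.y[k], self.angle[k] = xk, yk, ak
            # check against already placed only
            ok = True
            if placed:
                dx = self._min_image(self.x[:placed] - xk)
                dy = self._min_image(self.y[:placed] - yk)
                cand = np.flatnonzero(
                    dx * dx + dy * dy < (0.5 * (self.length[:placed] + self.length[k]) + p.width) ** 2
                )
                if cand.size:
                    a1, b1 = shaft_endpoints(0.0, 0.0, ak, self.length[k], p.width)
                    a2, b2 = shaft_endpoints(dx[cand], dy[cand], self.angle[cand], self.length[cand], p.width)
                    _, _, dist = segment_closest_points(
                        np.broadcast_to(a1, (cand.size, 2)), np.broadcast_to(b1, (cand.size, 2)), a2, b2
                    )
                    ok = not np.any(dist < p.width)
            if ok:
                placed += 1
        if self.box > self.target_box:
            self._compress_to(self.target_box)

    def _insert_aligned(self):
        """Rows of parallel rods laid end to end (first-fit decreasing).

        Rows run along x with random per-row phase; slack within each row and
        between rows is distributed evenly so the configuration is strictly
        overlap free under the periodic boundary.
        """
        p = self.params
        w = p.width
        order = np.argsort(-self.length)
        capacity = self.box * 0.995
        rows: list[list[int]] = []
        row_len: list[float] = []
        for k in order:
            placed = False
            for r, used in enumerate(row_len):
                if used + self.length[k] <= capacity:
                    rows[r].append(k)
                    row_len[r] += self.length[k]
                    placed = True
                    break
            if not placed:
                rows.append([k])
                row_len.append(self.length[k])
        n_rows = len(rows)
        if n_rows * (w + 0.02) > self.box:
            raise PackingError(
                f"cannot build an aligned dense packing of {p.n_particles} particles "
                f"at area fraction {p.area_fraction}"
            )
        dy = self.box / n_rows
        self.x = np.empty(p.n_particles)
        self.y = np.empty(p.n_particles)
        self.angle = np.zeros(p.n_particles)
        for r, members in enumerate(rows):
            yk = (r + 0.5) * dy
            slack = self.box - row_len[r]
            gap = slack / len(members)
            cursor = self.rng.uniform(0, self.box)
            for k in members:
                self.x[k] = (cursor + 0.5 * gap + 0.5 * self.length[k]) % self.box
                self.y[k] = yk
                cursor += self.length[k] + gap
        if self._any_overlap():  # defensive; construction should be valid
            raise PackingError("aligned dense packing construction produced overlaps")

    def _any_overlap(self) -> bool:
        return any(
            self._overlaps_any(k, self.x[k], self.y[k], self.angle[k])
            for k in range(self.params.n_particles)
        )

    def _resolve_overlaps(self, max_iter: int = 4000) -> bool:
        """Push overlapping pairs apart along contact normals (periodic).

        Athermal relaxation used during compression: displacements are split
        between the two particles and capped per iteration, with a
        contact-torque rotation that lets rods slide past each other.
        Returns True once the configuration is hard-core valid.
        """
        p = self.params
        w = p.width
        reach = self.length.max() + w
        cap = 0.25 * w
        for _ in range(max_iter):
            self.x %= self.box
            self.y %= self.box
            tree = cKDTree(np.column_stack([self.x, self.y]), boxsize=self.box)
            pairs = tree.query_pairs(reach, output_type="ndarray")
            if pairs.size == 0:
                return True
            i, j = pairs[:, 0], pairs[:, 1]
            dx = self._min_image(self.x[j] - self.x[i])
            dy = self._min_image(self.y[j] - self.y[i])
            a1, b1 = shaft_endpoints(np.zeros_like(dx), np.zeros_like(dy), self.angle[i], self.length[i], w)
            a2, b2 = shaft_endpoints(dx, dy, self.angle[j], self.length[j], w)
            c1, c2, dist = segment_closest_points(a1, b1, a2, b2)
            depth = w - dist
            act = depth > 0.0
            if not np.any(act):
                return True
            ia, ja = i[act], j[act]
            d = np.maximum(dist[act], 1e-9)[:, None]
            nvec = (c1[act] - c2[act]) / d  # points from j towards i
            degenerate = dist[act] < 1e-9
            if np.any(degenerate):
                ang = self.rng.uniform(0, 2 * np.pi, int(degenerate.sum()))
                nvec[degenerate] = np.column_stack([np.cos(ang), np.sin(ang)])
            # slight overshoot so the pair ends strictly separated
            move = np.minimum(0.5 * depth[act] + 1e-4 * w, cap)[:, None] * nvec
            ddx = np.zeros(p.n_particles)
            ddy = np.zeros(p.n_particles)
            np.add.at(ddx, ia, move[:, 0])
            np.add.at(ddy, ia, move[:, 1])
            np.add.at(ddx, ja, -move[:, 0])
            np.add.at(ddy, ja, -move[:, 1])
            tq = np.zeros(p.n_particles)
            fmag = depth[act][:, None] * nvec
            np.add.at(tq, ia, c1[act][:, 0] * fmag[:, 1] - c1[act][:, 1] * fmag[:, 0])
            rj = c2[act] - np.column_stack([dx[act], dy[act]])
            np.add.at(tq, ja, -(rj[:, 0] * fmag[:, 1] - rj[:, 1] * fmag[:, 0]))
            self.x += ddx
            self.y += ddy
            self.angle += np.clip(tq / self.length**2, -0.05, 0.05)
        return False

    def _compress_to(self, target: float, step: float = 0.99):
        """Shrink the box isotropically to ``target`` (jamming-style protocol).

        Each step rescales the box and positions, resolves the resulting
        overlaps athermally, and thermalizes with one Metropolis sweep; the
        final configuration is hard-core valid at the target density.
        """
        while self.box > target * (1 + 1e-12):
            s = max(step, target / self.box)
            self.box *= s
            self.x *= s
            self.y *= s
            if not self._resolve_overlaps():
                raise PackingError(
                    f"compression jammed at box {self.box:.2f} before target {target}"
                )
            self.sweep()

    # -- dynamics -----------------------------------------------------------
    def sweep(self):
        p = self.params
        order = self.rng.permutation(p.n_particles)
        moves = self.rng.uniform(-1, 1, size=(p.n_particles, 3))
        for k, mv in zip(order, moves):
            self.attempted += 1
            xk = (self.x[k] + mv[0] * p.max_trans) % self.box
            yk = (self.y[k] + mv[1] * p.max_trans) % self.box
            ak = self.angle[k] + mv[2] * p.max_rot
            if not self._overlaps_any(k, xk, yk, ak):
                self.x[k], self.y[k], self.angle[k] = xk, yk, ak
                self.accepted += 1

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / max(self.attempted, 1)

    def frame(self, time: float) -> ColonyFrame:
        p = self.params
        return ColonyFrame(
            time=time,
            ids=np.arange(p.n_particles),
            x=self.x.copy(),
            y=self.y.copy(),
            length=self.length.copy(),
            width=np.full(p.n_particles, p.width),
            angle=fold_angle(self.angle),
        )


def sample_passive_mc(params: MCParams) -> list:
    """Equilibrate and sample passive hard-spherocylinder configurations.

    Runs ``n_equil`` Metropolis sweeps, then returns a :class:`ColonyFrame`
    every ``sample_every`` sweeps up to ``n_sweeps``.
    """
    mc = PassiveMC(params)
    for _ in range(params.n_equil):
        mc.sweep()
    frames = []
    swept = params.n_equil
    while swept < params.n_equil + params.n_sweeps:
        for _ in range(params.sample_every):
            mc.sweep()
        swept += params.sample_every
        frames.append(mc.frame(time=float(swept)))
    return frames


def periodic_images(frame: ColonyFrame, box: float, margin: float) -> ColonyFrame:
    """Augment a periodic-box frame with image cells within ``margin`` of the walls.

    Useful before correlation analysis so rays leaving the box see the
    periodic continuation rather than vacuum.  Image cells get ids offset by
    multiples of ``10**ceil(log10(n))`` to stay unique.
    """
    xs, ys, Ls, Ws, angs, ids = [frame.x], [frame.y], [frame.length], [frame.width], [frame.angle], [frame.ids]
    offset = 10 ** int(np.ceil(np.log10(max(frame.n_cells, 2)))) + frame.ids.max() + 1
    tag = 1
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            if sx == 0 and sy == 0:
                continue
            nx = frame.x + sx * box
            ny = frame.y + sy * box
            keep = (nx > -margin) & (nx < box + margin) & (ny > -margin) & (ny < box + margin)
            if not np.any(keep):
                continue
            xs.append(nx[keep])
            ys.append(ny[keep])
            Ls.append(frame.length[keep])
            Ws.append(frame.width[keep])
            angs.append(frame.angle[keep])
            ids.append(frame.ids[keep] + tag * offset)
            tag += 1
    return ColonyFrame(
        time=frame.time,
        ids=np.concatenate(ids),
        x=np.concatenate(xs),
        y=np.concatenate(ys),
        length=np.concatenate(Ls),
        width=np.concatenate(Ws),
        angle=np.concatenate(angs),
    )


# ---------------------------------------------------------------------------
# analytic fixtures
# ---------------------------------------------------------------------------


def make_defect_field(charges: Sequence, grid, core_radius: float | None = None):
    """Analytic Q-tensor field with prescribed topological defects.

    ``charges`` is a sequence of ``((x, y), m, phase)`` with half-integer
    winding numbers ``m``.  The director angle is
    ``phi(r) = sum_k m_k atan2(y - y_k, x - x_k) + phase_k`` and the order
    parameter is ``S = 1`` with a smooth ``tanh(r_k / core_radius)`` cutoff
    at each core, so the winding of the director around each core is exactly
    ``m_k`` and the integrated charge density over a disc containing a single
    core equals ``m_k``.
    """
    from .fields import QTensorField  # local import to avoid cycle

    if core_radius is None:
        core_radius = 2.0 * grid.h
    pos = np.array([c[0] for c in charges], float).reshape(-1, 2)
    ms = np.array([c[1] for c in charges], float)
    phases = np.array([c[2] for c in charges], float)
    if ms.size and np.any(np.abs(2 * ms - np.round(2 * ms)) > 1e-9):
        raise ValueError("winding numbers must be half-integers")
    if ms.size and np.any(ms == 0):
        raise ValueError("winding numbers must be nonzero")
    if pos.shape[0] >= 2:
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() <= 4.0 * grid.h:
            raise ValueError("defect cores closer than 4 grid spacings; winding loops would overlap")

    X, Y = grid.meshgrid()
    phi = np.full(X.shape, phases.sum())
    S = np.ones_like(X)
    for (xk, yk), mk in zip(pos, ms):
        r = np.hypot(X - xk, Y - yk)
        phi = phi + mk * np.arctan2(Y - yk, X - xk)
        S = S * np.tanh(r / core_radius)
    return QTensorField(grid=grid, Qxx=S * np.cos(2 * phi), Qxy=S * np.sin(2 * phi))


def make_aligned_colony(
    n: int,
    angle: float = 0.0,
    length: float = 3.0,
    width: float = 0.9,
    gap: float = 0.1,
    angles=None,
    time: float = 0.0,
) -> ColonyFrame:
    """Pack ``n`` non-overlapping identical cells in rows at a common angle.

    ``angles`` optionally overrides the orientation per cell (positions are
    still laid out on the common-angle lattice, spaced to avoid overlap for
    any orientations).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ncols = int(np.ceil(np.sqrt(n)))
    pitch = length + gap if angles is None else length + gap  # safe for any angle
    row_pitch = (width + gap) if angles is None else (length + gap)
    xs, ys = [], []
    for k in range(n):
        row, col = divmod(k, ncols)
        xs.append(col * pitch)
        ys.append(row * row_pitch)
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    ca, sa = np.cos(angle), np.sin(angle)
    X = ca * xs - sa * ys
    Y = sa * xs + ca * ys
    if angles is None:
        ang = np.full(n, angle)
    else:
        ang = np.asarray(angles, float)
        if ang.shape != (n,):
            raise ValueError("angles must have length n")
    return ColonyFrame(
        time=time,
        ids=np.arange(n),
        x=X,
        y=Y,
        length=np.full(n, length),
        width=np.full(n, width),
        angle=ang,
    )


def two_cell_pair(
    length: float = 2.0,
    width: float = 1.0,
    arrangement: str = "side_by_side",
    gap: float = 0.1,
    angle: float = 0.0,
) -> ColonyFrame:
    """The two-cell calibration configuration for correlation lengths.

    ``side_by_side`` places the cells parallel with a lateral gap;
    ``end_on`` places them pole to pole along the common axis.
    """
    ca, sa = np.cos(angle), np.sin(angle)
    if arrangement == "side_by_side":
        off = np.array([-sa, ca]) * (width + gap)
    elif arrangement == "end_on":
        off = np.array([ca, sa]) * (length + gap)
    else:
        raise ValueError("arrangement must be 'side_by_side' or 'end_on'")
    return ColonyFrame(
        time=0.0,
        ids=np.array([0, 1]),
        x=np.array([0.0, off[0]]),
        y=np.array([0.0, off[1]]),
        length=np.full(2, length),
        width=np.full(2, width),
        angle=np.full(2, angle),
    )
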