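"""Finite-difference simulator of the growing dry active nematic.

The model couples three fields on a square grid: the cell density ``rho``,
the nematic tensor ``Q`` and the (diagnostic) velocity ``v``:

* mass conservation with uniform growth,
  ``d rho/dt = -div(rho v) + Lambda rho``;
* overdamped force balance against substrate friction,
  ``v = div(sigma) / (gamma rho)`` with stress
  ``sigma = -p I - a Q``, ``p = G max(rho/rho0 - 1, 0)``, ``a = a0 rho``;
* relaxational nematodynamics for ``Q`` with advection, co-rotation,
  flow alignment ``xi``, elastic diffusion ``Khat = K/gamma1`` and a
  density-dependent ordering term ``alpha(rho) Q - beta |Q|^2 Q`` with
  ``alpha = alpha0 (rho - rho0/2)`` and ``beta = alpha0 rho0 / 2`` so that
  ``2 S^2 = 1`` in the colony bulk.

Numerical guards follow the constitutive prescription: growth is switched
off where ``rho > 2 rho0`` and the velocity is zeroed where
``rho < rho0/2`` to avoid dividing by a vanishing density.  Time stepping is
explicit Euler with central differences (first-order upwind for the density
flux).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .fields import Grid, QTensorField

__all__ = [
    "SimParams",
    "FieldState",
    "active_stress",
    "solve_velocity",
    "step_density",
    "step_qtensor",
    "run_simulation",
    "run_until_radius",
    "colony_radius",
    "hubble_constant",
    "boundary_psi",
    "low_order_fraction",
    "turbulence_scan",
]


@dataclass
class SimParams:
    """Continuum model parameters (simulation units).

    Defaults reproduce the growing-colony regime at the onset of activity-
    driven disorder: ``Lambda = 0.001``, ``a0 = 0.02``,
    ``G = gamma = rho0 = 1``, ``alpha0 = Khat = 0.01``, ``xi = 0.7``.
    """

    Lambda: float = 0.001
    a0: float = 0.02
    G: float = 1.0
    gamma: float = 1.0
    rho0: float = 1.0
    alpha0: float = 0.01
    Khat: float = 0.01
    xi: float = 0.7
    beta: float | None = None  # default alpha0 * rho0 / 2
    rho_c: float | None = None  # default rho0 / 2
    n: int = 128
    dx: float = 1.0
    dt: float = 0.1
    init_radius: float = 10.0
    noise: float = 0.01
    seed: int = 0
    v_threshold: float | None = None  # default rho0 / 2
    growth_cap: float | None = None  # default 2 * rho0
    edge_margin: int = 10  # grid spacings the colony must keep from the box edge

    def __post_init__(self):
        if self.beta is None:
            self.beta = self.alpha0 * self.rho0 / 2.0
        if self.rho_c is None:
            self.rho_c = self.rho0 / 2.0
        if self.v_threshold is None:
            self.v_threshold = self.rho0 / 2.0
        if self.growth_cap is None:
            self.growth_cap = 2.0 * self.rho0
        for name in ("Lambda", "G", "gamma", "rho0", "alpha0", "Khat", "dx", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.a0 < 0:
            raise ValueError("a0 must be non-negative")
        # explicit-Euler stability: elastic diffusion of Q and the effective
        # pressure diffusion of rho (diffusivity ~ G / (gamma rho0))
        if self.dt >= self.dx**2 / (4.0 * self.Khat):
            raise ValueError("dt violates the Q-diffusion stability bound dx^2/(4 Khat)")
        if self.dt >= 0.25 * self.dx**2 * self.gamma * self.rho0 / self.G:
            raise ValueError("dt violates the pressure-diffusion stability bound")

    @property
    def grid(self) -> Grid:
        half = 0.5 * (self.n - 1) * self.dx
        return Grid(x0=-half, y0=-half, h=self.dx, nx=self.n, ny=self.n)


@dataclass
class FieldState:
    """Simulation state: density, order tensor and diagnostic velocity."""

    rho: np.ndarray
    Qxx: np.ndarray
    Qxy: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    time: float
    dx: float

    @property
    def S(self) -> np.ndarray:
        return np.hypot(self.Qxx, self.Qxy)

    def to_qtensor_field(self) -> QTensorField:
        ny, nx = self.rho.shape
        half_x = 0.5 * (nx - 1) * self.dx
        half_y = 0.5 * (ny - 1) * self.dx
        grid = Grid(x0=-half_x, y0=-half_y, h=self.dx, nx=nx, ny=ny)
        return QTensorField(grid=grid, Qxx=self.Qxx.copy(), Qxy=self.Qxy.copy())

    def copy(self) -> "FieldState":
        return FieldState(
            rho=self.rho.copy(),
            Qxx=self.Qxx.copy(),
            Qxy=self.Qxy.copy(),
            vx=self.vx.copy(),
            vy=self.vy.copy(),
            time=self.time,
            dx=self.dx,
        )


def _laplacian(a: np.ndarray, dx: float) -> np.ndarray:
    p = np.pad(a, 1, mode="edge")
    return (p[1:-1, 2:] + p[1:-1, :-2] + p[2:, 1:-1] + p[:-2, 1:-1] - 4.0 * a) / dx**2


def active_stress(state: FieldState, params: SimParams):
    """Stress tensor components ``(sxx, sxy, syy)``.

    ``sigma = -p I - a Q`` with ``p = G max(rho/rho0 - 1, 0)`` (pressure only
    above close packing) and extensile activity ``a = a0 rho``.
    """
    p = params.G * np.maximum(state.rho / params.rho0 - 1.0, 0.0)
    a = params.a0 * state.rho
    sxx = -p - a * state.Qxx
    syy = -p + a * state.Qxx
    sxy = -a * state.Qxy
    return sxx, sxy, syy


def solve_velocity(state: FieldState, params: SimParams):
    """Overdamped velocity ``v = div(sigma)/(gamma rho)``, zeroed at low density."""
    sxx, sxy, syy = active_stress(state, params)
    dx = state.dx
    dsxx_dy, dsxx_dx = np.gradient(sxx, dx)
    dsxy_dy, dsxy_dx = np.gradient(sxy, dx)
    dsyy_dy, dsyy_dx = np.gradient(syy, dx)
    denom = params.gamma * np.maximum(state.rho, 1e-12)
    vx = (dsxx_dx + dsxy_dy) / denom
    vy = (dsxy_dx + dsyy_dy) / denom
    low = state.rho < params.v_threshold
    vx[low] = 0.0
    vy[low] = 0.0
    return vx, vy


def step_density(state: FieldState, params: SimParams, dt: float) -> np.ndarray:
    """Conservative upwind update of the density (closed box boundaries)."""
    rho, vx, vy = state.rho, state.vx, state.vy
    ny, nx = rho.shape
    dx = state.dx
    fx = np.zeros((ny, nx + 1))
    vxf = 0.5 * (vx[:, :-1] + vx[:, 1:])
    fx[:, 1:-1] = np.where(vxf > 0, rho[:, :-1], rho[:, 1:]) * vxf
    fy = np.zeros((ny + 1, nx))
    vyf = 0.5 * (vy[:-1, :] + vy[1:, :])
    fy[1:-1, :] = np.where(vyf > 0, rho[:-1, :], rho[1:, :]) * vyf
    div = (fx[:, 1:] - fx[:, :-1]) / dx + (fy[1:, :] - fy[:-1, :]) / dx
    growth = np.where(rho < params.growth_cap, params.Lambda * rho, 0.0)
    new = rho + dt * (-div + growth)
    if new.min() < -1e-9:
        raise RuntimeError(
            f"density went negative ({new.min():.3g}); advective CFL violated — reduce dt"
        )
    np.clip(new, 0.0, None, out=new)
    return new


def step_qtensor(state: FieldState, params: SimParams, dt: float, rho: np.ndarray | None = None):
    """Explicit Euler update of ``(Qxx, Qxy)``; tracelessness is structural.

    ``rho`` defaults to the state's density (pass the updated density to use
    post-step ordering strength).
    """
    if rho is None:
        rho = state.rho
    dx = state.dx
    Qxx, Qxy, vx, vy = state.Qxx, state.Qxy, state.vx, state.vy
    dvx_dy, dvx_dx = np.gradient(vx, dx)
    dvy_dy, dvy_dx = np.gradient(vy, dx)
    uxy = 0.5 * (dvx_dy + dvy_dx)
    w = 0.5 * (dvx_dy - dvy_dx)  # omega_xy

    dQxx_dy, dQxx_dx = np.gradient(Qxx, dx)
    dQxy_dy, dQxy_dx = np.gradient(Qxy, dx)
    adv_xx = vx * dQxx_dx + vy * dQxx_dy
    adv_xy = vx * dQxy_dx + vy * dQxy_dy

    alpha = params.alpha0 * (rho - params.rho_c)
    q2 = 2.0 * (Qxx**2 + Qxy**2)

    new_xx = Qxx + dt * (
        -adv_xx
        + params.Khat * _laplacian(Qxx, dx)
        + alpha * Qxx
        - params.beta * q2 * Qxx
        + params.xi * 0.5 * (dvx_dx - dvy_dy)
        + 2.0 * w * Qxy
    )
    new_xy = Qxy + dt * (
        -adv_xy
        + params.Khat * _laplacian(Qxy, dx)
        + alpha * Qxy
        - params.beta * q2 * Qxy
        + params.xi * uxy
        - 2.0 * w * Qxx
    )
    if max(np.abs(new_xx).max(), np.abs(new_xy).max()) > 10.0:
        raise RuntimeError("Q-tensor diverged (|Q| > 10); time step unstable")
    return new_xx, new_xy


def initial_state(params: SimParams) -> FieldState:
    """Close-packed disc of radius ``init_radius`` with small Q noise inside."""
    rng = np.random.default_rng(params.seed)
    grid = params.grid
    X, Y = grid.meshgrid()
    r = np.hypot(X, Y)
    inside = r <= params.init_radius
    rho = np.where(inside, params.rho0, 0.0).astype(float)
    Qxx = np.where(inside, rng.uniform(-params.noise, params.noise, size=rho.shape), 0.0)
    Qxy = np.where(inside, rng.uniform(-params.noise, params.noise, size=rho.shape), 0.0)
    return FieldState(rho=rho, Qxx=Qxx, Qxy=Qxy, vx=np.zeros_like(rho), vy=np.zeros_like(rho), time=0.0, dx=params.dx)


def _advance(state: FieldState, params: SimParams, n_steps: int) -> FieldState:
    for _ in range(n_steps):
        state.vx, state.vy = solve_velocity(state, params)
        new_rho = step_density(state, params, params.dt)
        state.Qxx, state.Qxy = step_qtensor(state, params, params.dt, rho=new_rho)
        state.rho = new_rho
        state.time += params.dt
    return state


def _near_edge(state: FieldState, params: SimParams) -> bool:
    m = params.edge_margin
    band = np.concatenate(
        [
            state.rho[:m, :].ravel(),
            state.rho[-m:, :].ravel(),
            state.rho[:, :m].ravel(),
            state.rho[:, -m:].ravel(),
        ]
    )
    return bool(band.max() > 0.1 * params.rho0)


def run_simulation(params: SimParams, t_end: float, snapshot_every: float | None = None) -> list:
    """Integrate from the standard initial condition to ``t_end``.

    Returns the list of snapshots (including the initial and final states).
    Deterministic for a given seed.  Stops early with a warning if the colony
    approaches the box edge.
    """
    state = initial_state(params)
    snaps = [state.copy()]
    if snapshot_every is None:
        snapshot_every = t_end
    steps_per_snap = max(int(round(snapshot_every / params.dt)), 1)
    n_total = int(round(t_end / params.dt))
    done = 0
    while done < n_total:
        k = min(steps_per_snap, n_total - done)
        _advance(state, params, k)
        done += k
        snaps.append(state.copy())
        if _near_edge(state, params):
            warnings.warn("colony reached the box-edge margin; stopping early")
            break
    return snaps


def run_until_radius(params: SimParams, target_radius: float, check_every: float = 20.0, t_max: float | None = None) -> FieldState:
    """Integrate until the colony radius reaches ``target_radius``."""
    if t_max is None:
        t_max = 6.0 * np.log(max(target_radius / params.init_radius, 1.5)) / params.Lambda
    state = initial_state(params)
    steps = max(int(round(check_every / params.dt)), 1)
    while state.time < t_max:
        _advance(state, params, steps)
        if colony_radius(state, params) >= target_radius:
            return state
        if _near_edge(state, params):
            warnings.warn("colony reached the box-edge margin before the target radius")
            return state
    warnings.warn("t_max reached before the target radius")
    return state


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def colony_radius(state: FieldState, params: SimParams) -> float:
    """Effective radius from the area where ``rho > rho0/2``."""
    area = np.count_nonzero(state.rho > 0.5 * params.rho0) * state.dx**2
    return float(np.sqrt(area / np.pi))


def _radii(state: FieldState):
    ny, nx = state.rho.shape
    x = (np.arange(nx) - 0.5 * (nx - 1)) * state.dx
    y = (np.arange(ny) - 0.5 * (ny - 1)) * state.dx
    X, Y = np.meshgrid(x, y)
    return X, Y, np.hypot(X, Y)


def hubble_constant(state: FieldState, params: SimParams, fit_fraction: float = 0.8):
    """Slope of the azimuthally averaged radial velocity inside the colony."""
    from .order import hubble_fit

    X, Y, r = _radii(state)
    R = colony_radius(state, params)
    sel = (state.rho > 0.5 * params.rho0) & (r < fit_fraction * R) & (r > 1e-9)
    vr = (state.vx[sel] * X[sel] + state.vy[sel] * Y[sel]) / r[sel]
    fit = hubble_fit(r[sel], vr, bin_width=2.0 * state.dx, r_fit_max=fit_fraction * R)
    return fit


def boundary_psi(state: FieldState, params: SimParams) -> np.ndarray:
    """Acute angle (deg) between director and boundary tangent on the interface.

    The interface band is ``0.25 rho0 < rho < 0.75 rho0``; the tangent is
    perpendicular to the density gradient.
    """
    dx = state.dx
    drho_dy, drho_dx = np.gradient(state.rho, dx)
    band = (state.rho > 0.25 * params.rho0) & (state.rho < 0.75 * params.rho0)
    S = state.S
    band &= S > 1e-3
    gnorm = np.hypot(drho_dx, drho_dy)
    band &= gnorm > 1e-9
    if not np.any(band):
        return np.array([])
    nang = 0.5 * np.arctan2(state.Qxy[band], state.Qxx[band])
    tx, ty = -drho_dy[band] / gnorm[band], drho_dx[band] / gnorm[band]
    dot = np.abs(np.cos(nang) * tx + np.sin(nang) * ty)
    return np.degrees(np.arccos(np.clip(dot, 0.0, 1.0)))


def low_order_fraction(
    state: FieldState,
    params: SimParams,
    cutoff: float = 0.25,
    interior_fraction: float = 0.75,
):
    """Fraction of interior colony points with low order (``2 S^2 < cutoff``).

    The interior excludes the boundary ring (radius below
    ``interior_fraction`` of the colony radius and density above
    ``0.75 rho0``); the cutoff 0.25 corresponds to ``S`` below half its bulk
    value.
    """
    _, _, r = _radii(state)
    R = colony_radius(state, params)
    interior = (r < interior_fraction * R) & (state.rho > 0.75 * params.rho0)
    n_int = np.count_nonzero(interior)
    if n_int == 0:
        return np.nan, np.nan
    low = 2.0 * state.S[interior] ** 2 < cutoff
    frac = float(np.count_nonzero(low) / n_int)
    area_density = float(np.count_nonzero(low) / (n_int * state.dx**2))
    return frac, area_density


def turbulence_scan(
    base_params: SimParams,
    a0_values,
    target_radius: float = 28.0,
    low_order_cutoff: float = 0.01,
) -> dict:
    """Locate the onset of interior defect proliferation across activities.

    Each activity ``a0`` is run to the same colony radius; the onset is the
    first value whose interior low-order fraction exceeds
    ``low_order_cutoff``.  Reports the dimensionless control parameter
    ``a0 rho0 / (gamma_hat Khat) = a0 / (gamma Khat)`` at onset and domain-
    size estimates ``l_a ~ density^(-1/2)`` for the turbulent runs.
    """
    a0_values = sorted(a0_values)
    if len(a0_values) < 2:
        raise ValueError("need at least two activity values to bracket the onset")
    fractions, densities, control = [], [], []
    for a0 in a0_values:
        p = replace(base_params, a0=a0)
        state = run_until_radius(p, target_radius)
        frac, dens = low_order_fraction(state, p)
        fractions.append(frac)
        densities.append(dens)
        control.append(a0 * p.rho0 / (p.gamma * p.rho0 * p.Khat))
    fractions = np.asarray(fractions)
    above = np.flatnonzero(fractions > low_order_cutoff)
    if above.size == 0 or above[0] == 0:
        raise RuntimeError("activity range does not bracket the turbulence onset")
    onset_idx = int(above[0])
    la = [1.0 / np.sqrt(d) if (np.isfinite(d) and d > 0) else np.nan for d in densities]
    return {
        "a0": np.asarray(a0_values, float),
        "control_parameter": np.asarray(control),
        "low_order_fraction": fractions,
        "low_order_density": np.asarray(densities),
        "l_a": np.asarray(la),
        "onset_a0": float(a0_values[onset_idx]),
        "onset_control_parameter": float(control[onset_idx]),
    }
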