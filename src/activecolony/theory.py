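"""Closed-form theory of the growing dry active nematic.

Pure functions implementing the analytic results that accompany the
simulator: the Hubble relation ``H = Lambda/2`` from ``div v = Lambda``, the
stress-propagation length ``l_sigma = sqrt(G/(gamma_hat Lambda))``, the 1D
colony stress profile, the torque on a misaligned rod and the resulting
alignment rates in 1D and 2D, the bulk nematic fixed point, and order-of-
magnitude length-scale estimates.

Units are SI throughout this module (s, m, Pa); converters to and from the
experiment-facing micrometre/minute units are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import quad

__all__ = [
    "MaterialParams",
    "RadialGrowthProfile",
    "per_min_to_per_s",
    "per_s_to_per_min",
    "um_to_m",
    "m_to_um",
    "hubble_prediction",
    "stress_propagation_length",
    "stress_profile_1d",
    "stress_profile_curvature",
    "torque_1d",
    "alignment_rate_1d",
    "alignment_rate_2d",
    "bulk_order_fixed_point",
    "screening_length",
    "active_length_estimates",
    "turbulence_control_parameter",
]

SECONDS_PER_MINUTE = 60.0
METRES_PER_MICRON = 1e-6


def per_min_to_per_s(rate_per_min: float) -> float:
    return rate_per_min / SECONDS_PER_MINUTE


def per_s_to_per_min(rate_per_s: float) -> float:
    return rate_per_s * SECONDS_PER_MINUTE


def um_to_m(length_um: float) -> float:
    return length_um * METRES_PER_MICRON


def m_to_um(length_m: float) -> float:
    return length_m / METRES_PER_MICRON


@dataclass
class MaterialParams:
    """Material parameters of the colony, SI units.

    Defaults are order-of-magnitude estimates for *E. coli* microcolonies on
    agarose: cell-wall stress scale ``G ~ 3 kPa``, areal friction
    ``gamma_hat = gamma L rho ~ 1e15 Pa s / m^2``, growth rate
    ``Lambda = 0.014 / min``.
    """

    G: float = 3.0e3  # stress scale (Pa)
    gamma_hat: float = 1.0e15  # areal friction gamma*L*rho (Pa s m^-2)
    Lambda: float = per_min_to_per_s(0.014)  # growth rate (1/s)
    gamma: float = 1.0e11  # friction per unit length (Pa s / m)
    zeta: float = 1.0  # single-cell rotational drag (N m s per rad)
    L: float = um_to_m(4.0)  # cell length (m)
    P0: float = 0.0  # boundary pressure (Pa)
    xi: float = 0.7  # flow-alignment coupling (dimensionless)
    S: float = 1.0 / np.sqrt(2.0)  # bulk scalar order parameter
    eta: float = 1.0  # effective colony viscosity (Pa s), estimate only

    def __post_init__(self):
        for name in ("G", "gamma_hat", "Lambda", "gamma", "zeta", "L", "eta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RadialGrowthProfile:
    """Local growth rate ``g(r)`` and its derivative ``g'(r)``.

    The radial expansion velocity is ``v_r = g(r) r``; uniform area growth
    corresponds to ``g = Lambda/2`` with ``g' = 0``, in which case growth
    exerts no net aligning torque on the director.
    """

    g: Callable[[float], float]
    gprime: Callable[[float], float]

    @classmethod
    def uniform(cls, Lambda: float) -> "RadialGrowthProfile":
        return cls(g=lambda r: 0.5 * Lambda, gprime=lambda r: 0.0)


def hubble_prediction(Lambda: float) -> float:
    """Expansion coefficient ``H`` of the radial flow ``v_r = H r``.

    Uniform exponential growth imposes ``div v = Lambda``; in two dimensions
    the radially symmetric solution is ``v_r = (Lambda/2) r``, so
    ``H = Lambda / 2``.
    """
    if Lambda < 0:
        raise ValueError("Lambda must be non-negative")
    return 0.5 * Lambda


def stress_propagation_length(G: float, gamma_hat: float, Lambda: float) -> float:
    """``l_sigma = sqrt(G / (gamma_hat Lambda))``.

    Growth stress spreads diffusively with diffusivity ``G/gamma_hat``; the
    spread during one doubling time ``1/Lambda`` defines this length.
    """
    if min(G, gamma_hat, Lambda) <= 0:
        raise ValueError("G, gamma_hat and Lambda must be positive")
    return float(np.sqrt(G / (gamma_hat * Lambda)))


def stress_profile_1d(params: MaterialParams, y0: float, y) -> np.ndarray:
    """Stress ``sigma_yy`` in a 1D colony occupying ``0 < y < y0``.

    Force balance ``d sigma_yy / dy = gamma_hat v_y`` with ``v_y = Lambda y``
    and boundary condition ``sigma_yy(y0) = -P0`` gives

    ``sigma_yy(y) = -P0 - (Lambda gamma_hat / 2)(y0^2 - y^2)``,

    compressive and largest in magnitude at the colony centre.
    """
    y = np.asarray(y, float)
    if y0 <= 0:
        raise ValueError("y0 must be positive")
    if np.any(y < 0) or np.any(y > y0):
        raise ValueError("y must lie in [0, y0]")
    return -params.P0 - 0.5 * params.Lambda * params.gamma_hat * (y0**2 - y**2)


def stress_profile_curvature(params: MaterialParams) -> float:
    """Second derivative of the 1D stress profile, ``gamma_hat Lambda``."""
    return params.gamma_hat * params.Lambda


def torque_1d(
    params: MaterialParams,
    theta: float,
    y0: float,
    v_y: Callable[[float], float] | None = None,
) -> float:
    """Frictional torque on a rod at height ``y0`` tilted by ``theta``.

    Quadrature of ``integral_{-L/2}^{L/2} gamma v_y(y0 + l sin theta)
    l cos theta dl``.  ``v_y`` defaults to the growth flow
    ``v_y(y) = Lambda y``, for which the integral evaluates to
    ``gamma Lambda L^3 sin(2 theta) / 24``.
    """
    if v_y is None:
        v_y = lambda y: params.Lambda * y  # noqa: E731
    ct, st = np.cos(theta), np.sin(theta)
    half = 0.5 * params.L

    def integrand(l):
        return params.gamma * v_y(y0 + l * st) * l * ct

    val, err = quad(integrand, -half, half)
    if not np.isfinite(val) or err > 1e-8 * max(abs(val), 1.0):
        raise RuntimeError("torque quadrature did not converge")
    return float(val)


def alignment_rate_1d(params: MaterialParams, theta: float, dv_dy: float) -> float:
    """``d theta/dt = (gamma L^3 / 24 zeta) (dv_y/dy) sin(2 theta)``.

    With an extensional flow (``dv_dy > 0``) the rod rotates towards
    ``theta = 90 deg`` (alignment perpendicular to the extension gradient is
    the stable fixed point).
    """
    return params.gamma * params.L**3 / (24.0 * params.zeta) * dv_dy * np.sin(2.0 * theta)


def alignment_rate_2d(
    xi: float,
    g_profile: RadialGrowthProfile,
    r: float,
    S: float,
    theta: float,
    phi: float,
) -> float:
    """``d theta/dt = (xi g'(r) r / 4 S) sin 2(theta - phi)`` in 2D.

    ``phi`` is the azimuthal angle of the point.  For uniform growth
    (``g' = 0``, the incompressible case) the rate vanishes for every
    orientation; ``g' < 0`` makes tangential alignment
    (``theta = phi + pi/2``) stable, ``g' > 0`` makes radial alignment
    stable.
    """
    if S <= 0:
        raise ValueError("S must be positive")
    gp = g_profile.gprime(r)
    return xi * gp * r / (4.0 * S) * np.sin(2.0 * (theta - phi))


def bulk_order_fixed_point(alpha0: float, rho: float, rho_c: float, beta: float) -> float:
    """Stable scalar order parameter ``S*`` of the bulk Q dynamics.

    From ``dQ/dt = alpha(rho) Q - beta |Q|^2 Q`` with
    ``alpha = alpha0 (rho - rho_c)`` and ``|Q|^2 = 2 S^2``:
    ``2 S*^2 = max(alpha/beta, 0)``.  With the standard choice
    ``beta = alpha0 rho0/2`` and ``rho_c = rho0/2``, a bulk at ``rho = rho0``
    sits at ``2 S*^2 = 1``.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    alpha = alpha0 * (rho - rho_c)
    return float(np.sqrt(0.5 * max(alpha / beta, 0.0)))


def screening_length(eta: float, gamma_hat: float) -> float:
    """Hydrodynamic screening length ``l_s = sqrt(eta / gamma_hat)``.

    Above this scale substrate friction dominates internal viscous stresses
    and the dry (momentum non-conserving) description applies.  Reporting-
    only estimate.
    """
    if min(eta, gamma_hat) <= 0:
        raise ValueError("eta and gamma_hat must be positive")
    return float(np.sqrt(eta / gamma_hat))


def active_length_estimates(
    K: float | None = None,
    a: float | None = None,
    L: float | None = None,
    Khat: float | None = None,
    alpha0: float | None = None,
    a0: float | None = None,
    gamma_hat: float | None = None,
    rho: float | None = None,
) -> dict:
    """Alternative estimates of the active instability length ``l_a``.

    The functional form of ``l_a`` in the dry, growing system is uncertain,
    so three labeled estimates are reported (NaN where inputs are missing):

    - ``"wet_balance"``: ``sqrt(K/a)`` — balance of Frank elasticity and
      active stress, the wet-limit scaling;
    - ``"cell_scale"``: ``L`` — with ``K ~ G L^2`` and ``a ~ G``, ``K/a``
      is a constant and ``l_a`` tracks the cell length;
    - ``"dry_relaxational"``: ``sqrt(Khat/(alpha0 rho)) *
      sqrt(gamma_hat Khat/(a0 rho))`` — the nematic coherence length reduced
      by the inverse square root of the turbulence control parameter.
    """
    out = {"wet_balance": np.nan, "cell_scale": np.nan, "dry_relaxational": np.nan}
    if K is not None and a is not None and a > 0:
        out["wet_balance"] = float(np.sqrt(K / a))
    if L is not None:
        out["cell_scale"] = float(L)
    if None not in (Khat, alpha0, a0, gamma_hat, rho) and min(alpha0, a0, rho) > 0:
        coherence = np.sqrt(Khat / (alpha0 * rho))
        control = a0 * rho / (gamma_hat * Khat)
        if control > 0:
            out["dry_relaxational"] = float(coherence / np.sqrt(control))
    return out


def turbulence_control_parameter(a0: float, rho: float, gamma_hat: float, Khat: float) -> float:
    """Dimensionless onset parameter ``a0 rho / (gamma_hat Khat)``.

    Active turbulence (defect proliferation in the colony interior) sets in
    when this exceeds a threshold of order 2.
    """
    if min(gamma_hat, Khat) <= 0:
        raise ValueError("gamma_hat and Khat must be positive")
    return float(a0 * rho / (gamma_hat * Khat))
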