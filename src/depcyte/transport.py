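"""Creeping-flow particle transport over the DEP actuation region.

Micron-scale particles in this device have particle Reynolds and Stokes
numbers far below one, so inertia is neglected and the force balance gives
instantaneous velocities (overdamped dynamics):

    v_px = v_m(h) + F_DEP,x / (6 pi eta r lambda_par(h))
    v_ph = (F_DEP,h + F_lift + F_grav+buoy) / (6 pi eta r lambda_perp(h))

with v_m the parabolic laminar profile and lambda_perp / lambda_par the
wall-induced drag enhancements for motion perpendicular / parallel to the
channel walls.  The vertical force budget comprises DEP, hydrodynamic lift,
and net gravity-buoyancy.  The trajectory is integrated with x as the
independent variable (a tracked particle always advances downstream), and
the incoming/outgoing velocities vi/vo are least-squares slopes of x(t)
over windows before and after the electrode pair -- exactly the observable
the video tracker measures.

Hydrodynamic lift.  The lift on a sphere translating in shear flow between
walls is modelled as a short-range wall repulsion

    F_lift = 6 C eta v_mean r^3 / gap^2 * exp(-gap / ell) * tanh(z / delta)

where gap is the particle-surface-to-nearest-wall distance, z = H/2 - h,
C = 0.31 the lift coefficient, ell a screening length (default 1.0 um) and
delta a small regularization width making the mid-channel null continuous.
The screening makes the repulsion lubrication-like: strong within a couple
of microns of a wall, negligible in the channel core.  With the device's
nominal parameters this places the no-DEP equilibrium of a CHO-sized cell
at heights where the undisturbed transport velocity is ~900-1100 um/s,
the band in which the instrument operates.  Because the true functional
form of the lift is an approximation, ``lift_model`` is pluggable: the
unscreened inverse-square form and a bounded "plateau" form are provided.

Coordinates: h is the height of the particle *center* above the channel
floor; z = H/2 - h appears only when mirroring printed formulas.  Vertical
forces are signed, positive upward.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .dielectrics import Medium
from .field_solver import FieldGrid, dep_force

__all__ = [
    "ParticleState",
    "TransportParams",
    "VelocityObservation",
    "Trajectory",
    "fluid_velocity",
    "gravity_buoyancy",
    "lift_force",
    "wall_drag_lambda",
    "wall_parallel_lambda",
    "equilibrium_height",
    "simulate_trajectory",
    "check_overdamped",
    "LIFT_MODELS",
]

G = 9.81  # m/s^2

#: Minimum particle-surface-to-wall gap (m) used to clamp the lift
#: singularity when a trajectory grazes a wall.
MIN_GAP = 10e-9


@dataclass(frozen=True)
class ParticleState:
    """Particle center position and time."""

    x: float
    h: float
    t: float = 0.0


@dataclass(frozen=True)
class VelocityObservation:
    """Fitted incoming/outgoing velocities (m/s) and their difference."""

    vi: float
    vo: float
    flags: tuple[str, ...] = ()

    @property
    def v_diff(self) -> float:
        return self.vi - self.vo


def _gap_and_direction(h: float, r: float, H: float,
                       smoothing: float) -> tuple[float, float]:
    gap = min(h, H - h) - r
    if gap <= MIN_GAP:
        warnings.warn("particle in wall contact; lift gap clamped", stacklevel=4)
        gap = MIN_GAP
    direction = math.tanh((H / 2.0 - h) / smoothing)
    return gap, direction


def _lift_screened(h, r, v_mean, eta, H, C, smoothing, ell=1.0e-6):
    gap, direction = _gap_and_direction(h, r, H, smoothing)
    return 6.0 * C * eta * v_mean * r ** 3 / gap ** 2 * math.exp(-gap / ell) * direction


def _lift_inverse_square(h, r, v_mean, eta, H, C, smoothing):
    gap, direction = _gap_and_direction(h, r, H, smoothing)
    return 6.0 * C * eta * v_mean * r ** 3 / gap ** 2 * direction


def _lift_plateau(h, r, v_mean, eta, H, C, smoothing):
    _, direction = _gap_and_direction(h, r, H, smoothing)
    return 6.0 * C * eta * v_mean * r ** 3 / H ** 2 * direction


#: Selectable lift force laws (see module docstring).
LIFT_MODELS: dict[str, Callable] = {
    "screened": _lift_screened,
    "inverse_square": _lift_inverse_square,
    "plateau": _lift_plateau,
}


@dataclass(frozen=True)
class TransportParams:
    """Everything the trajectory integrator needs besides the field.

    ``lift_model`` selects among :data:`LIFT_MODELS` by name or accepts a
    callable with signature (h, r, v_mean, eta, H, C, smoothing) returning a
    signed vertical force in newtons (positive up).
    """

    medium: Medium
    radius: float
    re_kcm: float
    particle_density: float = 1050.0  # kg/m^3
    mean_flow_velocity: float = 1.0e-3  # m/s
    channel_height: float = 50e-6  # m
    lift_coefficient: float = 0.31
    gravity: float = G
    centerline_smoothing: float = 0.5e-6  # m, tanh width of the lift null
    lift_model: Union[str, Callable] = "screened"
    parallel_wall_correction: bool = True

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.channel_height <= 0:
            raise ValueError("radius and channel height must be positive")
        if not -0.5 - 1e-9 <= self.re_kcm <= 1.0 + 1e-9:
            raise ValueError("Re{Kcm} must lie in [-0.5, 1]")
        if self.radius >= self.channel_height / 2:
            raise ValueError("particle does not fit in the channel")
        if isinstance(self.lift_model, str) and self.lift_model not in LIFT_MODELS:
            raise ValueError(f"unknown lift model {self.lift_model!r}")

    def lift(self, h: float) -> float:
        fun = (LIFT_MODELS[self.lift_model]
               if isinstance(self.lift_model, str) else self.lift_model)
        return fun(h, self.radius, self.mean_flow_velocity,
                   self.medium.viscosity, self.channel_height,
                   self.lift_coefficient, self.centerline_smoothing)

    def net_weight(self) -> float:
        return gravity_buoyancy(self.radius, self.particle_density,
                                self.medium.mass_density, self.gravity)

    def stokes_drag_coefficient(self) -> float:
        return 6.0 * math.pi * self.medium.viscosity * self.radius


def fluid_velocity(h, v_mean: float, H: float):
    """Parabolic laminar profile 6*v_mean*(h/H)*(1 - h/H); its mean over the
    channel height equals v_mean."""
    h = np.asarray(h, dtype=float)
    if np.any((h < 0) | (h > H)):
        raise ValueError("height outside channel")
    out = 6.0 * v_mean * (h / H) * (1.0 - h / H)
    return float(out) if out.ndim == 0 else out


def gravity_buoyancy(r: float, rho_p: float, rho_m: float,
                     g: float = G) -> float:
    """Signed net gravity-buoyancy force (N), positive up.

    Magnitude (4/3)*pi*g*r^3*|rho_p - rho_m|; directed toward the floor when
    the particle is denser than the medium.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    return -(4.0 / 3.0) * math.pi * g * r ** 3 * (rho_p - rho_m)


def lift_force(h: float, r: float, v_mean: float, eta: float, H: float,
               C: float = 0.31, smoothing: float = 0.5e-6,
               model: str = "screened") -> float:
    """Signed hydrodynamic lift force (N), positive up.

    Vanishes at mid-channel, points away from the nearest wall, and (for the
    default model) decays with a 1.0 um screening length away from the wall.
    """
    if not (r <= h <= H - r):
        raise ValueError("particle overlaps a wall")
    return LIFT_MODELS[model](h, r, v_mean, eta, H, C, smoothing)


def _single_wall_perp(s: float) -> float:
    """Perpendicular-mobility wall correction 1/(1 - 9/8 s + 1/2 s^3),
    s = r / (particle-center-to-wall distance); truncated
    method-of-reflections series with first-order coefficient 9/8."""
    return 1.0 / (1.0 - 1.125 * s + 0.5 * s ** 3)


def _single_wall_par(s: float) -> float:
    """Parallel-mobility (Faxen) wall correction 1/(1 - 9/16 s + 1/8 s^3)."""
    return 1.0 / (1.0 - 0.5625 * s + 0.125 * s ** 3)


def wall_drag_lambda(h: float, r: float, H: float) -> float:
    """Two-wall perpendicular drag enhancement lambda >= 1.

    Product of truncated single-wall corrections for floor and ceiling;
    tends to 1 in the unbounded limit and grows steeply as either wall is
    approached.  Symmetric: lambda(h) = lambda(H - h).
    """
    if not (r < min(h, H - h)):
        raise ValueError("particle overlapping wall")
    return _single_wall_perp(r / h) * _single_wall_perp(r / (H - h))


def wall_parallel_lambda(h: float, r: float, H: float) -> float:
    """Two-wall parallel (downstream) drag enhancement lambda >= 1."""
    if not (r < min(h, H - h)):
        raise ValueError("particle overlapping wall")
    return _single_wall_par(r / h) * _single_wall_par(r / (H - h))


def equilibrium_height(params: TransportParams) -> float:
    """Height in (r, H/2] where lift balances net weight (no DEP).

    For a particle denser than the medium, the wall repulsion (diverging at
    floor contact, vanishing at mid-channel) crosses the net weight at a
    unique height below the centerline, located by bisection.  If the lift
    cannot support the particle anywhere the near-floor bound is returned;
    if it exceeds the weight everywhere (buoyant particle) the centerline.
    """
    r, H = params.radius, params.channel_height
    w = params.net_weight()  # < 0 for sinking particles

    def net(h):
        return params.lift(h) + w

    lo = r + max(10 * MIN_GAP, 1e-8)
    hi = H / 2.0
    if net(lo) <= 0:
        return lo
    if net(hi) >= 0:
        return hi
    return brentq(net, lo, hi, xtol=1e-10)


def check_overdamped(params: TransportParams) -> dict:
    """Particle Reynolds and Stokes numbers at the configured operating
    point; both must be << 1 for the inertialess force balance to hold."""
    rho_m = params.medium.mass_density
    eta = params.medium.viscosity
    r, v = params.radius, params.mean_flow_velocity
    re_p = rho_m * v * 2 * r / eta
    tau = (2 * r ** 2 * params.particle_density) / (9 * eta)
    stokes = tau * v / (2 * r)
    numbers = {"reynolds": re_p, "stokes": stokes}
    if re_p > 0.1 or stokes > 0.1:
        warnings.warn(f"overdamped assumption questionable: {numbers}")
    return numbers


@dataclass
class Trajectory:
    """Integrated particle path with the fitted velocity observation."""

    x: np.ndarray  # m
    h: np.ndarray  # m
    t: np.ndarray  # s
    captured: bool = False
    observation: VelocityObservation = None

    def to_frame(self):
        import pandas as pd

        vx = np.gradient(self.x, self.t)
        return pd.DataFrame({"t_s": self.t, "x_m": self.x,
                             "h_m": self.h, "vx_m_per_s": vx})


def _slope(t: np.ndarray, x: np.ndarray) -> float:
    """OLS slope of x against t."""
    t = t - t.mean()
    return float(t @ (x - x.mean()) / (t @ t))


def simulate_trajectory(entry: ParticleState, params: TransportParams,
                        fieldgrid: FieldGrid, x_span: float,
                        exclusion_margin: float = 50e-6,
                        rtol: float = 1e-6,
                        n_samples: int = 400,
                        max_step: float | None = None) -> Trajectory:
    """Integrate the overdamped force balance from ``entry`` over ``x_span``.

    The electrode pair position is taken from ``fieldgrid.layout``; vi and
    vo are OLS slopes of x(t) over [x_start, x_e1 - margin] and
    [x_e2 + margin, x_end].  A particle whose downstream velocity falls to
    zero (strong pDEP trapping at an electrode edge) is flagged
    ``captured`` and its vo left undefined.
    """
    r, H = params.radius, params.channel_height
    drag = params.stokes_drag_coefficient()
    weight = params.net_weight()
    v_mean = params.mean_flow_velocity
    x0, x1 = entry.x, entry.x + x_span
    if not (r < entry.h < H - r):
        raise ValueError("entry height must place the particle inside the channel")
    if x0 < fieldgrid.x[0] or x1 > fieldgrid.x[-1]:
        raise ValueError("field grid does not cover the requested x span")

    h_lo = r + MIN_GAP
    h_hi = H - r - MIN_GAP
    use_par = params.parallel_wall_correction

    def velocities(x, h):
        h = min(max(h, h_lo), h_hi)
        ge2 = fieldgrid.grad_e2_at(x, h)
        f_dep = dep_force(r, params.re_kcm, params.medium, ge2)
        lam_par = wall_parallel_lambda(h, r, H) if use_par else 1.0
        vx = fluid_velocity(h, v_mean, H) + f_dep[0] / (drag * lam_par)
        lam = wall_drag_lambda(h, r, H)
        vh = (f_dep[1] + params.lift(h) + weight) / (drag * lam)
        return vx, vh

    def rhs(x, y):
        vx, vh = velocities(x, y[0])
        vx = max(vx, 1e-9)  # event below stops the solve before this binds
        return [vh / vx, 1.0 / vx]

    def stalled(x, y):
        vx, _ = velocities(x, y[0])
        return vx - 1e-6  # m/s; effectively zero downstream motion

    stalled.terminal = True
    stalled.direction = -1

    sol = solve_ivp(rhs, (x0, x1), [entry.h, entry.t], method="RK45",
                    rtol=rtol, atol=[1e-10, 1e-9], dense_output=True,
                    events=[stalled],
                    max_step=max_step or fieldgrid.layout.gap / 5.0)
    if not sol.success:
        raise RuntimeError(f"trajectory integration failed: {sol.message}")
    captured = bool(sol.t_events[0].size)
    x_end = sol.t[-1]

    xs = np.linspace(x0, x_end, n_samples)
    hh, tt = sol.sol(xs)
    hh = np.clip(hh, h_lo, h_hi)

    x_e1, x_e2 = fieldgrid.layout.span
    flags = []
    pre = xs <= x_e1 - exclusion_margin
    post = xs >= x_e2 + exclusion_margin
    vi = _slope(tt[pre], xs[pre]) if pre.sum() >= 3 else math.nan
    vo = _slope(tt[post], xs[post]) if post.sum() >= 3 else math.nan
    if captured:
        flags.append("captured")
    if math.isnan(vi) or math.isnan(vo):
        flags.append("partial")
    obs = VelocityObservation(vi=vi, vo=vo, flags=tuple(flags))
    return Trajectory(x=xs, h=hh, t=tt, captured=captured, observation=obs)
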