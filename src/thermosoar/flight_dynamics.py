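"""Point-mass glider dynamics with a quasi-steady aerodynamic closure.

The glider is a point mass described by position (x, y, z) and its
*air-relative* velocity in polar form: speed V, glide angle gamma (below
the horizon) and side angle chi (heading).  Controls are the bank angle
sigma, the angle-of-attack alpha, and the sideslip angle beta (carried in
the force model but zero in the nominal configuration).  Equations of
motion, with the local air velocity w = (wx, wy, wz)::

    dx/dt   =  V cos(chi) cos(gamma) + wx
    dy/dt   =  V sin(chi) cos(gamma) + wy
    dz/dt   =  V sin(gamma)          + wz
    dV/dt   = -D/m - g sin(gamma)
    dgamma/dt = (L cos(sigma) + C sin(sigma)) / (m V) - (g/V) cos(gamma)
    dchi/dt = (L sin(sigma) - C cos(sigma)) / (m V cos(gamma))

The aerodynamic forces act on the air-relative velocity, so the
(V, gamma, chi) block is the familiar still-air glider set; the air
motion enters through the position kinematics, which is what lets a
thermal lift the glider: circling at radius R inside an updraft w(R)
climbs at dz/dt = V sin(gamma) + w(R).  Wind-gradient terms
(accelerations of the air along the path) are neglected — the
quasi-steady assumption for slowly varying fields; dynamic-soaring
effects are out of scope.  The ground velocity, e.g. for GPS-style
logging or the agent's speed sensor, is the air-relative vector plus the
local air velocity.

Aerodynamic closure: linear lift curve C_L = C_L0 + C_Lalpha * alpha,
quadratic drag polar C_D = C_D0 + k_ind * C_L^2, linear side-force law
C_Y = C_Ybeta * beta, all on the air-relative speed V.

The shipped "vulture" preset (m = 7.75 kg, S = 0.87 m^2) carries effective
coefficients calibrated against two performance anchors: best straight
glide of -0.75 m/s at (sigma=0, alpha=6 deg) — which is also the min-sink
point — and an optimal steady-circle climb of 0.72 m/s in the reference
thermal (w*=5 m/s, z*=2000 m, evaluated at z=500 m).  See
:func:`calibrate_coefficients`.

Angles at this interface are degrees (radians internally); integration is
classical fixed-step RK4 at 0.05 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

from .atmosphere import AirVelocity

__all__ = [
    "GliderParams",
    "GliderState",
    "ControlState",
    "AeroForces",
    "InstabilityError",
    "PitchMonitor",
    "aerodynamic_forces",
    "derivatives",
    "step",
    "integrate",
    "detect_instability",
    "vulture_params",
    "nominal_params",
    "calibrate_coefficients",
]

RHO_SEA_LEVEL = 1.225  # kg/m^3, standard air density
PHYSICS_DT = 0.05  # s, internal integration step
V_MIN = 2.0  # m/s, stall/singularity guard
GAMMA_MAX_DEG = 90.0  # +-limit on the glide angle before the model is singular


class InstabilityError(RuntimeError):
    """Raised when the dynamics leave the model's domain of validity."""


@dataclass(frozen=True)
class GliderParams:
    """Mass, geometry and effective aerodynamic coefficients.

    Angles in the coefficient laws are radians; ``c_l0``/``c_lalpha`` define
    the lift curve, ``c_d0``/``k_ind`` the drag polar, ``c_ybeta`` the
    side-force slope (negative: sideslip produces a restoring side force).
    """

    m: float = 7.75  # kg
    S: float = 0.87  # m^2
    g: float = 9.81  # m/s^2
    rho: float = RHO_SEA_LEVEL  # kg/m^3
    c_l0: float = 0.27234370343627734
    c_lalpha: float = 2.0  # per rad
    c_d0: float = 0.00524181960247941
    k_ind: float = 0.06800764263759139
    c_ybeta: float = -0.5  # per rad

    def __post_init__(self) -> None:
        if min(self.m, self.S, self.g, self.rho) <= 0:
            raise ValueError("m, S, g, rho must be positive")
        if self.c_d0 <= 0 or self.k_ind < 0:
            raise ValueError("drag polar must give D > 0 for V > 0")

    def lift_coefficient(self, alpha_rad: float) -> float:
        return self.c_l0 + self.c_lalpha * alpha_rad

    def drag_coefficient(self, alpha_rad: float) -> float:
        cl = self.lift_coefficient(alpha_rad)
        return self.c_d0 + self.k_ind * cl * cl


def vulture_params() -> GliderParams:
    """Vulture-like glider: m = 7.75 kg, S = 0.87 m^2, calibrated polar."""
    return GliderParams()


def nominal_params() -> GliderParams:
    """Alias for the nominal configuration (same as the vulture preset)."""
    return GliderParams()


@dataclass(frozen=True)
class GliderState:
    """Continuous physical state.  Angles in radians, SI units.

    V, gamma, chi describe the air-relative velocity; position rates add
    the local air velocity on top (see the module docstring).
    """

    x: float
    y: float
    z: float
    V: float
    gamma: float
    chi: float

    @property
    def vz(self) -> float:
        """Air-relative climb rate V sin(gamma) (add w_z for ground climb)."""
        return self.V * math.sin(self.gamma)

    def velocity(self) -> tuple[float, float, float]:
        """Air-relative velocity vector."""
        cg = math.cos(self.gamma)
        return (
            self.V * math.cos(self.chi) * cg,
            self.V * math.sin(self.chi) * cg,
            self.V * math.sin(self.gamma),
        )

    def ground_velocity(self, air: AirVelocity) -> tuple[float, float, float]:
        vx, vy, vz = self.velocity()
        return (vx + air.vx, vy + air.vy, vz + air.vz)


@dataclass(frozen=True)
class ControlState:
    """Aerodynamic angles in degrees (interface convention)."""

    sigma: float = 0.0  # bank angle, [-50, 50]
    alpha: float = 6.0  # angle-of-attack, [-30, 30]
    beta: float = 0.0  # sideslip, 0 in the nominal configuration

    SIGMA_LIMIT = 50.0
    ALPHA_LIMIT = 30.0

    def clipped(self) -> "ControlState":
        return ControlState(
            sigma=min(max(self.sigma, -self.SIGMA_LIMIT), self.SIGMA_LIMIT),
            alpha=min(max(self.alpha, -self.ALPHA_LIMIT), self.ALPHA_LIMIT),
            beta=self.beta,
        )


@dataclass(frozen=True)
class AeroForces:
    """Lift, drag and side force (N)."""

    L: float
    D: float
    C: float


def aerodynamic_forces(
    state: GliderState,
    ctrl: ControlState,
    air: AirVelocity,
    p: GliderParams,
) -> AeroForces:
    """Quasi-steady forces on the air-relative speed.

    ``state.V`` *is* the air-relative speed (the ``air`` argument is kept
    for interface symmetry with :func:`derivatives`; it does not enter
    the force magnitudes).  Raises :class:`InstabilityError` when the
    airspeed is not positive (the quasi-steady model is singular there).
    """
    v_air = state.V
    if v_air <= 0.0:
        raise InstabilityError("non-positive airspeed")
    alpha = math.radians(ctrl.alpha)
    beta = math.radians(ctrl.beta)
    q = 0.5 * p.rho * p.S * v_air * v_air
    cl = p.lift_coefficient(alpha)
    return AeroForces(
        L=q * cl,
        D=q * (p.c_d0 + p.k_ind * cl * cl),
        C=q * p.c_ybeta * beta,
    )


def derivatives(
    state: GliderState,
    ctrl: ControlState,
    air: AirVelocity,
    p: GliderParams,
) -> tuple[float, float, float, float, float, float]:
    """Time derivatives (dx, dy, dz, dV, dgamma, dchi)."""
    cg = math.cos(state.gamma)
    if abs(cg) < 1e-9 or abs(state.gamma) >= math.radians(GAMMA_MAX_DEG):
        raise InstabilityError("glide angle at +-90 deg: heading is singular")
    if state.V <= 0.0:
        raise InstabilityError("non-positive airspeed")
    f = aerodynamic_forces(state, ctrl, air, p)
    sg = math.sin(state.gamma)
    sig = math.radians(ctrl.sigma)
    cs, ss = math.cos(sig), math.sin(sig)
    dx = state.V * math.cos(state.chi) * cg + air.vx
    dy = state.V * math.sin(state.chi) * cg + air.vy
    dz = state.V * sg + air.vz
    dV = -f.D / p.m - p.g * sg
    dgamma = (f.L * cs + f.C * ss) / (p.m * state.V) - p.g * cg / state.V
    dchi = (f.L * ss - f.C * cs) / (p.m * state.V * cg)
    return (dx, dy, dz, dV, dgamma, dchi)


WindField = Callable[[float, float, float, float], AirVelocity]
"""Air velocity as a function of (x, y, z, t)."""

STILL_AIR: WindField = lambda x, y, z, t: AirVelocity(0.0, 0.0, 0.0)


def step(
    state: GliderState,
    ctrl: ControlState,
    wind_field: WindField,
    t: float,
    dt: float = PHYSICS_DT,
    p: Optional[GliderParams] = None,
) -> GliderState:
    """One classical RK4 step of length ``dt`` starting at time ``t``.

    Raises :class:`InstabilityError` if the dynamics become singular
    (propagated from :func:`derivatives`) or the speed drops below the
    stall guard ``V_MIN``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if p is None:
        p = vulture_params()
    new = _rk4_tuple(
        (state.x, state.y, state.z, state.V, state.gamma, state.chi),
        ctrl, wind_field, t, dt, p,
    )
    return GliderState(*new)


_GAMMA_MAX_RAD = math.radians(GAMMA_MAX_DEG)


def _deriv_tuple(s, ctrl: ControlState, wind_field: "WindField", t: float,
                 p: GliderParams):
    """Allocation-light derivative evaluation on a plain state tuple."""
    x, y, z, V, gamma, chi = s
    cg = math.cos(gamma)
    if abs(cg) < 1e-9 or abs(gamma) >= _GAMMA_MAX_RAD:
        raise InstabilityError("glide angle at +-90 deg: heading is singular")
    if V <= 0.0:
        raise InstabilityError("non-positive ground speed")
    air = wind_field(x, y, z, t)
    sg = math.sin(gamma)
    cc, sc = math.cos(chi), math.sin(chi)
    alpha = math.radians(ctrl.alpha)
    beta = math.radians(ctrl.beta)
    q = 0.5 * p.rho * p.S * V * V
    cl = p.c_l0 + p.c_lalpha * alpha
    L = q * cl
    D = q * (p.c_d0 + p.k_ind * cl * cl)
    C = q * p.c_ybeta * beta
    sig = math.radians(ctrl.sigma)
    cs, ss = math.cos(sig), math.sin(sig)
    return (
        V * cc * cg + air.vx,
        V * sc * cg + air.vy,
        V * sg + air.vz,
        -D / p.m - p.g * sg,
        (L * cs + C * ss) / (p.m * V) - p.g * cg / V,
        (L * ss - C * cs) / (p.m * V * cg),
    )


def _rk4_tuple(s, ctrl, wind_field, t, dt, p):
    h2 = dt / 2.0
    k1 = _deriv_tuple(s, ctrl, wind_field, t, p)
    s2 = tuple(a + h2 * b for a, b in zip(s, k1))
    k2 = _deriv_tuple(s2, ctrl, wind_field, t + h2, p)
    s3 = tuple(a + h2 * b for a, b in zip(s, k2))
    k3 = _deriv_tuple(s3, ctrl, wind_field, t + h2, p)
    s4 = tuple(a + dt * b for a, b in zip(s, k3))
    k4 = _deriv_tuple(s4, ctrl, wind_field, t + dt, p)
    h6 = dt / 6.0
    new = tuple(
        a + h6 * (b + 2 * c + 2 * d + e)
        for a, b, c, d, e in zip(s, k1, k2, k3, k4)
    )
    if new[3] < V_MIN:
        raise InstabilityError(f"speed below stall guard ({new[3]:.2f} m/s)")
    if abs(new[4]) >= _GAMMA_MAX_RAD:
        raise InstabilityError("glide angle reached +-90 deg")
    return new


def integrate(
    state: GliderState,
    ctrl: ControlState,
    wind_field: WindField,
    t0: float,
    duration: float,
    dt: float = PHYSICS_DT,
    p: Optional[GliderParams] = None,
    monitor: Optional["PitchMonitor"] = None,
) -> GliderState:
    """Integrate under constant controls for ``duration`` seconds."""
    n = max(1, round(duration / dt))
    h = duration / n
    s, t = state, t0
    for _ in range(n):
        s = step(s, ctrl, wind_field, t, h, p)
        t += h
        if monitor is not None and monitor.update(s.gamma):
            raise InstabilityError("pitch wound through 360 deg")
    return s


class PitchMonitor:
    """Tracks same-direction winding of the glide angle at the physics rate.

    The instability criterion is cumulative: increments of gamma in a
    consistent direction accumulate; a change of direction restarts the
    count.  Reaching 360 degrees flags a pitch spin.  (Singularities
    — V below the stall guard or |gamma| at 90 deg — are raised directly by
    the integrator.)
    """

    def __init__(self, gamma0: float = 0.0):
        self._prev = gamma0
        self._wound = 0.0

    def update(self, gamma: float) -> bool:
        d = gamma - self._prev
        self._prev = gamma
        if d == 0.0:
            return False
        if self._wound == 0.0 or (d > 0) == (self._wound > 0):
            self._wound += d
        else:
            self._wound = d
        return abs(self._wound) >= 2.0 * math.pi

    @property
    def wound_deg(self) -> float:
        return math.degrees(self._wound)


def detect_instability(
    pitch_history: Sequence[float],
    state: Optional[GliderState] = None,
) -> bool:
    """True when the pitch history winds 360 deg in one direction or the
    state is singular (V <= V_MIN or |gamma| >= 90 deg).

    ``pitch_history`` is a sequence of glide angles (radians) sampled at the
    physics rate.
    """
    if state is not None:
        if state.V <= V_MIN or abs(state.gamma) >= math.radians(GAMMA_MAX_DEG):
            return True
    if len(pitch_history) >= 2:
        mon = PitchMonitor(pitch_history[0])
        for gam in pitch_history[1:]:
            if mon.update(gam):
                return True
    return False


def calibrate_coefficients(
    c_lalpha: float = 2.0,
    vz_baseline: float = -0.75,
    vz_optimal: float = 0.72,
    alpha_best_deg: float = 6.0,
) -> GliderParams:
    """Solve (C_L0, C_D0, k_ind) from the glider's performance anchors.

    Constraints: (i) the steady straight glide at (sigma=0, alpha =
    ``alpha_best_deg``) sinks at ``vz_baseline``; (ii) that alpha is the
    min-sink point (the baseline is the *best* achievable glide); (iii) the
    optimal constant-control circle in the reference thermal climbs at
    ``vz_optimal``.  The shipped preset stores the solution of the default
    arguments; this function exists to document and reproduce it.
    """
    from scipy.optimize import fsolve

    from .metrics import optimal_climb_rate, steady_straight_glide
    from .atmosphere import ThermalParams

    def resid(x):
        cl0, cd0, kind = x
        if cd0 <= 0 or kind < 0:
            return [1e3, 1e3, 1e3]
        p = GliderParams(c_l0=cl0, c_lalpha=c_lalpha, c_d0=cd0, k_ind=kind)
        vz6 = steady_straight_glide(alpha_best_deg, p).vz
        dvz = (
            steady_straight_glide(alpha_best_deg + 0.001, p).vz
            - steady_straight_glide(alpha_best_deg - 0.001, p).vz
        ) / 0.002
        opt, _ = optimal_climb_rate(p, ThermalParams(), z=500.0)
        return [vz6 - vz_baseline, dvz * 10.0, opt - vz_optimal]

    seed = GliderParams()
    sol = fsolve(resid, [seed.c_l0, seed.c_d0, seed.k_ind], xtol=1e-12)
    return GliderParams(
        c_l0=float(sol[0]),
        c_lalpha=c_lalpha,
        c_d0=float(sol[1]),
        k_ind=float(sol[2]),
    )
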