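"""Soaring-efficiency metric and the climb-rate bounds that define it.

The efficiency of a soaring flight is measured against two reference climb
rates of the same glider:

* ``vz_baseline`` — the best steady straight glide with no updraft (a sink,
  -0.75 m/s for the vulture preset, reached at sigma=0, alpha=6 deg);
* ``vz_optimal`` — the best climb achievable in the reference thermal by a
  steady constant-control circle (0.72 m/s for the vulture preset in the
  w*=5 m/s, z*=2000 m thermal at z=500 m).

    eta = (vz_agent - vz_baseline) / (vz_optimal - vz_baseline)

eta = 1 means the full updraft is exploited, eta = 0 is no better than
gliding straight, eta < 0 is worse than that.

The steady-state solvers are closed-form.  Under constant (sigma, alpha)
in still air (equivalently, in the frame moving with a uniform wind) the
force balance

    L cos(sigma) = m g cos(gamma),   D = -m g sin(gamma)

gives the dynamic pressure directly, hence speed, glide angle, turn radius
and sink rate without iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .atmosphere import ThermalParams, updraft
from .flight_dynamics import GliderParams, vulture_params

__all__ = [
    "EfficiencyBounds",
    "SteadyGlide",
    "SteadyCircle",
    "PerformanceSummary",
    "efficiency_eta",
    "steady_straight_glide",
    "steady_circle",
    "baseline_climb_rate",
    "optimal_climb_rate",
    "fraction_in_thermal",
    "summarize",
    "fit_thermal_params",
    "vulture_bounds",
]

THERMAL_MEMBERSHIP_RADIUS = 80.0  # m; updraft still positive inside


@dataclass(frozen=True)
class EfficiencyBounds:
    vz_optimal: float
    vz_baseline: float

    def __post_init__(self) -> None:
        if not self.vz_optimal > self.vz_baseline:
            raise ValueError("bounds must satisfy vz_optimal > vz_baseline")


def vulture_bounds() -> EfficiencyBounds:
    """Bounds of the calibrated vulture preset in the reference thermal."""
    p = vulture_params()
    opt, _ = optimal_climb_rate(p, ThermalParams(), z=500.0)
    return EfficiencyBounds(vz_optimal=opt, vz_baseline=baseline_climb_rate(p))


def efficiency_eta(vz_agent: float, bounds: EfficiencyBounds) -> float:
    """Fraction of the available updraft exploited; may exceed [0, 1]."""
    return (vz_agent - bounds.vz_baseline) / (
        bounds.vz_optimal - bounds.vz_baseline
    )


@dataclass(frozen=True)
class SteadyGlide:
    V: float  # ground speed, m/s
    gamma: float  # glide angle, rad (negative: descending)
    vz: float  # sink rate, m/s


@dataclass(frozen=True)
class SteadyCircle:
    V: float
    gamma: float
    radius: float  # m
    vz_sink: float  # still-air sink while circling, m/s
    sigma: float  # deg
    alpha: float  # deg


def steady_straight_glide(alpha_deg: float, p: GliderParams) -> SteadyGlide:
    """Steady wings-level glide at fixed angle-of-attack, still air."""
    cl = p.lift_coefficient(math.radians(alpha_deg))
    if cl <= 0:
        raise ValueError("no steady glide: non-positive lift coefficient")
    cd = p.drag_coefficient(math.radians(alpha_deg))
    q = p.m * p.g / math.hypot(cl, cd)
    V = math.sqrt(2.0 * q / (p.rho * p.S))
    gamma = math.asin(-q * cd / (p.m * p.g))
    return SteadyGlide(V=V, gamma=gamma, vz=V * math.sin(gamma))


def _steady_circle_arrays(sigma_deg, alpha_deg, p: GliderParams):
    """Vectorized steady-circle solution; radius is inf where sigma == 0."""
    sigma = np.radians(sigma_deg)
    alpha = np.radians(alpha_deg)
    cl = p.c_l0 + p.c_lalpha * alpha
    cd = p.c_d0 + p.k_ind * cl**2
    q = p.m * p.g / np.sqrt(cl**2 * np.cos(sigma) ** 2 + cd**2)
    V = np.sqrt(2.0 * q / (p.rho * p.S))
    singam = np.clip(-q * cd / (p.m * p.g), -1.0, 1.0)
    gamma = np.arcsin(singam)
    with np.errstate(divide="ignore"):
        radius = np.where(
            np.sin(sigma) > 0,
            p.m * V**2 * np.cos(gamma) ** 2 / (q * cl * np.sin(sigma)),
            np.inf,
        )
    return V, gamma, radius, V * singam, cl


def steady_circle(sigma_deg: float, alpha_deg: float, p: GliderParams) -> SteadyCircle:
    """Steady constant-control circle in still air (sigma > 0)."""
    if not sigma_deg > 0:
        raise ValueError("steady circle requires sigma > 0")
    V, gamma, radius, vz, cl = _steady_circle_arrays(
        np.float64(sigma_deg), np.float64(alpha_deg), p
    )
    if not (cl > 0 and np.isfinite(radius) and radius > 0):
        raise ValueError("no steady circle for this (sigma, alpha)")
    return SteadyCircle(
        V=float(V),
        gamma=float(gamma),
        radius=float(radius),
        vz_sink=float(vz),
        sigma=float(sigma_deg),
        alpha=float(alpha_deg),
    )


def baseline_climb_rate(p: GliderParams, alpha_deg: float = 6.0) -> float:
    """Steady-glide climb rate (a sink) at sigma=0 and the given alpha."""
    return steady_straight_glide(alpha_deg, p).vz


def optimal_climb_rate(
    p: GliderParams,
    t: ThermalParams,
    z: float = 500.0,
    sigma_range: tuple[float, float] = (0.0, 50.0),
    alpha_range: tuple[float, float] = (-5.0, 15.0),
    grid_step: float = 0.5,
) -> tuple[float, SteadyCircle]:
    """Upper bound on the climb rate in a thermal at altitude ``z``.

    Scans constant-control steady circles over the (sigma, alpha) box, adds
    the updraft at the circle radius, and refines the gridded argmax by
    golden-section search along each axis.  Returns the best net climb and
    the maximizing circle.
    """
    sig = np.arange(sigma_range[0], sigma_range[1] + 1e-9, grid_step)
    alp = np.arange(alpha_range[0], alpha_range[1] + 1e-9, grid_step)
    SG, AL = np.meshgrid(sig, alp, indexing="ij")
    V, gamma, radius, vz, cl = _steady_circle_arrays(SG, AL, p)
    ok = np.isfinite(radius) & (radius > 0) & (cl > 0)
    if not ok.any():
        raise ValueError("no feasible steady circle in the search box")
    net = np.where(ok, vz + updraft(np.where(ok, radius, 1.0), z, t), -np.inf)
    i, j = np.unravel_index(int(np.argmax(net)), net.shape)

    def net_climb(sigma_deg: float, alpha_deg: float) -> float:
        V_, g_, r_, vz_, cl_ = _steady_circle_arrays(
            np.float64(sigma_deg), np.float64(alpha_deg), p
        )
        if not (cl_ > 0 and np.isfinite(r_) and r_ > 0):
            return -np.inf
        return float(vz_ + updraft(float(r_), z, t))

    def golden(f, lo, hi, tol=1e-7):
        invphi = (math.sqrt(5.0) - 1.0) / 2.0
        a, b = lo, hi
        c, d = b - invphi * (b - a), a + invphi * (b - a)
        fc, fd = f(c), f(d)
        while b - a > tol:
            if fc > fd:
                b, d, fd = d, c, fc
                c = b - invphi * (b - a)
                fc = f(c)
            else:
                a, c, fc = c, d, fd
                d = a + invphi * (b - a)
                fd = f(d)
        return (a + b) / 2.0

    s_best, a_best = float(SG[i, j]), float(AL[i, j])
    for _ in range(3):  # alternate 1-D refinements
        s_lo = max(sigma_range[0], s_best - grid_step)
        s_hi = min(sigma_range[1], s_best + grid_step)
        s_best = golden(lambda s: net_climb(s, a_best), s_lo, s_hi)
        a_lo = max(alpha_range[0], a_best - grid_step)
        a_hi = min(alpha_range[1], a_best + grid_step)
        a_best = golden(lambda a: net_climb(s_best, a), a_lo, a_hi)
    best = net_climb(s_best, a_best)
    circ = steady_circle(s_best, a_best, p) if s_best > 0 else None
    if circ is None:
        raise ValueError("optimal circle degenerate (sigma = 0)")
    return best, circ


# ---------------------------------------------------------------------------
# Trajectory performance summaries


@dataclass
class PerformanceSummary:
    """Aggregate statistics over a set of trajectories."""

    mean_vz: float
    eta: float
    fraction_in_thermal: float
    mean_distance_to_center: float
    n_trajectories: int
    mean_duration: float = float("nan")  # s of flight per episode
    position_hist: Optional[pd.DataFrame] = None  # center-relative (x, y)
    vz_theta_hist: Optional[pd.DataFrame] = None  # (theta bin, vz bin)
    per_run_vz: Optional[np.ndarray] = None
    per_run_eta: Optional[np.ndarray] = None
    per_run_fraction: Optional[np.ndarray] = None


def _center_offsets(traj: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Glider position relative to the drifted thermal center."""
    if {"center_x", "center_y"}.issubset(traj.columns):
        cx, cy = traj["center_x"].to_numpy(), traj["center_y"].to_numpy()
    elif "u" in traj.columns:
        cx = traj["u"].to_numpy() * traj["t"].to_numpy()
        cy = np.zeros(len(traj))
    else:
        cx = cy = np.zeros(len(traj))
    return traj["x"].to_numpy() - cx, traj["y"].to_numpy() - cy


def fraction_in_thermal(
    traj: pd.DataFrame, radius: float = THERMAL_MEMBERSHIP_RADIUS
) -> float:
    """Fraction of 1 Hz samples within ``radius`` of the thermal center."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    dx, dy = _center_offsets(traj)
    return float(np.mean(np.hypot(dx, dy) <= radius))


def _mean_vz(traj: pd.DataFrame) -> float:
    if "vz" in traj.columns:
        return float(traj["vz"].mean())
    dt = np.diff(traj["t"].to_numpy())
    return float(np.mean(np.diff(traj["z"].to_numpy()) / dt))


def summarize(
    trajs: Iterable[pd.DataFrame],
    bounds: Optional[EfficiencyBounds] = None,
    position_extent: float = 100.0,
    position_bin: float = 5.0,
    vz_range: tuple[float, float] = (-4.0, 4.0),
    vz_bin: float = 0.25,
    theta_bin: float = 15.0,
) -> PerformanceSummary:
    """Fig-2-style summary: position and climb-vs-theta histograms.

    Binning is deterministic: fixed edges derived from the arguments.  An
    empty trajectory set yields an empty summary (NaN means, zero counts).
    """
    trajs = list(trajs)
    pos_edges = np.arange(-position_extent, position_extent + 1e-9, position_bin)
    th_edges = np.arange(-180.0, 180.0 + 1e-9, theta_bin)
    vz_edges = np.arange(vz_range[0], vz_range[1] + 1e-9, vz_bin)
    pos_counts = np.zeros((len(pos_edges) - 1, len(pos_edges) - 1))
    vt_counts = np.zeros((len(th_edges) - 1, len(vz_edges) - 1))
    vzs, fracs, dists = [], [], []
    for traj in trajs:
        dx, dy = _center_offsets(traj)
        h, _, _ = np.histogram2d(dx, dy, bins=(pos_edges, pos_edges))
        pos_counts += h
        if "theta" in traj.columns and "vz" in traj.columns:
            h2, _, _ = np.histogram2d(
                traj["theta"].to_numpy(),
                traj["vz"].to_numpy(),
                bins=(th_edges, vz_edges),
            )
            vt_counts += h2
        vzs.append(_mean_vz(traj))
        fracs.append(fraction_in_thermal(traj))
        dists.append(float(np.mean(np.hypot(dx, dy))))
    mean_vz = float(np.mean(vzs)) if vzs else float("nan")
    eta = (
        efficiency_eta(mean_vz, bounds)
        if bounds is not None and vzs
        else float("nan")
    )
    pos_index = pd.Index(pos_edges[:-1], name="x_edge")
    return PerformanceSummary(
        mean_vz=mean_vz,
        eta=eta,
        fraction_in_thermal=float(np.mean(fracs)) if fracs else float("nan"),
        mean_distance_to_center=float(np.mean(dists)) if dists else float("nan"),
        n_trajectories=len(trajs),
        position_hist=pd.DataFrame(
            pos_counts, index=pos_index, columns=pos_edges[:-1]
        ),
        vz_theta_hist=pd.DataFrame(
            vt_counts,
            index=pd.Index(th_edges[:-1], name="theta_edge"),
            columns=vz_edges[:-1],
        ),
        per_run_vz=np.asarray(vzs),
        per_run_eta=(
            np.asarray([efficiency_eta(v, bounds) for v in vzs])
            if bounds is not None
            else None
        ),
        per_run_fraction=np.asarray(fracs),
    )


def fit_thermal_params(
    target_mean_vz: float,
    target_radius: float,
    p: GliderParams,
    w_star_grid: Optional[Sequence[float]] = None,
    z_star_grid: Optional[Sequence[float]] = None,
    z: float = 500.0,
    rel_tolerance: float = 0.25,
) -> tuple[ThermalParams, float]:
    """Invert the optimal-climb solver for thermal parameters.

    Finds the (w*, z*) grid point whose optimal climb rate and optimal
    circling radius best match the targets (least squares on the
    relative-residual 2-vector).  Returns the best parameters and the
    residual norm; raises if the targets are degenerate, and reports (does
    not hide) a poor fit via the returned residual, warning if it exceeds
    ``rel_tolerance``.
    """
    if target_radius <= 0:
        raise ValueError("target radius must be positive")
    if w_star_grid is None:
        w_star_grid = np.arange(1.0, 10.01, 0.25)
    if z_star_grid is None:
        z_star_grid = np.arange(600.0, 3000.01, 100.0)
    best: tuple[float, ThermalParams] = (float("inf"), ThermalParams())
    for ws in w_star_grid:
        for zs in z_star_grid:
            tp = ThermalParams(w_star=float(ws), z_star=float(zs))
            if z >= zs / 1.1:  # no positive updraft at the working altitude
                continue
            try:
                vz_opt, circ = optimal_climb_rate(p, tp, z=z)
            except ValueError:
                continue
            r1 = (vz_opt - target_mean_vz) / max(abs(target_mean_vz), 0.1)
            r2 = (circ.radius - target_radius) / target_radius
            resid = math.hypot(r1, r2)
            if resid < best[0]:
                best = (resid, tp)
    if not math.isfinite(best[0]):
        raise ValueError("no feasible thermal parameters on the grid")
    if best[0] > rel_tolerance:
        import warnings

        warnings.warn(
            f"thermal-parameter fit residual {best[0]:.3f} exceeds "
            f"{rel_tolerance}: targets may be infeasible",
            stacklevel=2,
        )
    return best[1], best[0]
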