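"""Kinematic estimators for 1 Hz soaring tracks.

These operate on position-only trajectories — the format of GPS tracks of
soaring birds as well as of the simulator's logged output — and recover
quantities that are not directly observed: the bank angle (from the
centripetal acceleration), the horizontal wind (from the net drift of the
circling pattern), and the local thermalling diameter (from the geometry
of consecutive upwind/downwind crossings).

A trajectory here is a pandas DataFrame with at least columns
``t, x, y, z`` sampled at a uniform 1 s interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EstimatorOutput",
    "estimate_bank",
    "estimate_wind",
    "theta_series",
    "thermalling_diameter",
    "select_thermalling_segments",
]

LOW_CURVATURE_AR = 0.2  # m/s^2; mean radial acceleration below this warns


@dataclass
class EstimatorOutput:
    """Container for per-trajectory estimator results."""

    sigma_hat: float | None = None  # deg, trajectory mean
    wind_hat: np.ndarray | None = None  # (2,) m/s
    diameters: np.ndarray = field(default_factory=lambda: np.empty(0))
    a_r: np.ndarray = field(default_factory=lambda: np.empty(0))
    warnings: list[str] = field(default_factory=list)


def _check_uniform(traj: pd.DataFrame) -> float:
    t = traj["t"].to_numpy(dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-6):
        raise ValueError("estimators require uniform sampling")
    return float(dt[0])


def estimate_bank(traj: pd.DataFrame, g: float = 9.81) -> EstimatorOutput:
    """Mean bank angle from the track's radial acceleration.

    In steady banked circling the horizontal force balance gives
    ``tan(sigma) = a_r / g`` once drag and the small vertical acceleration
    are neglected.  The radial acceleration is taken as the component of
    the second-difference acceleration perpendicular to the planar
    velocity; ``sigma`` is computed per timestep and averaged over the
    trajectory.

    Straight tracks give sigma ~ 0 with a low-curvature warning attached.
    """
    dt = _check_uniform(traj)
    x = traj["x"].to_numpy(dtype=float)
    y = traj["y"].to_numpy(dtype=float)
    # central differences on the interior points
    vx = (x[2:] - x[:-2]) / (2 * dt)
    vy = (y[2:] - y[:-2]) / (2 * dt)
    ax = (x[2:] - 2 * x[1:-1] + x[:-2]) / dt**2
    ay = (y[2:] - 2 * y[1:-1] + y[:-2]) / dt**2
    speed = np.hypot(vx, vy)
    ok = speed > 1e-9
    a_r = np.zeros(len(ax))
    a_r[ok] = np.abs(vx[ok] * ay[ok] - vy[ok] * ax[ok]) / speed[ok]
    out = EstimatorOutput(a_r=a_r)
    out.sigma_hat = float(np.degrees(np.mean(np.arctan2(a_r, g))))
    if np.mean(a_r) < LOW_CURVATURE_AR:
        out.warnings.append("low curvature: trajectory is nearly straight")
    return out


def estimate_wind(traj: pd.DataFrame) -> EstimatorOutput:
    """Horizontal wind as the mean planar velocity over the trajectory.

    Over whole circles the circling component averages out and the mean
    velocity is the drift, i.e. the wind.  To avoid the bias of a partial
    final circle, the average is taken over the largest whole number of
    turns from the start of the track (located by interpolating the
    unwrapped heading); the full-track mean is used only when the track
    has less than one turn.  The estimate is exactly translation-invariant
    and rotation-equivariant.  A warning is attached when the track covers
    fewer than two full turns.
    """
    dt = _check_uniform(traj)
    t = traj["t"].to_numpy(dtype=float)
    x = traj["x"].to_numpy(dtype=float)
    y = traj["y"].to_numpy(dtype=float)
    vx = np.diff(x) / dt
    vy = np.diff(y) / dt
    heading = np.unwrap(np.arctan2(vy, vx))
    total = heading[-1] - heading[0]
    n_turns = int(abs(total) // (2 * math.pi))
    out = EstimatorOutput()
    if n_turns >= 1:
        target = heading[0] + math.copysign(2 * math.pi * n_turns, total)
        tm = 0.5 * (t[:-1] + t[1:])  # velocity sample times
        # last time the unwrapped heading passes the whole-turn mark
        idx = np.nonzero(
            (heading[:-1] - target) * (heading[1:] - target) <= 0
        )[0]
        i = int(idx[-1])
        frac = (target - heading[i]) / (heading[i + 1] - heading[i])
        t_star = tm[i] + frac * (tm[i + 1] - tm[i])
        x_star = np.interp(t_star, t, x)
        y_star = np.interp(t_star, t, y)
        span = t_star - t[0]
        out.wind_hat = np.array(
            [(x_star - x[0]) / span, (y_star - y[0]) / span]
        )
    else:
        out.wind_hat = np.array([np.mean(vx), np.mean(vy)])
    if abs(total) < 4 * math.pi:
        out.warnings.append("fewer than 2 full circles: wind estimate biased")
        warnings.warn(out.warnings[-1], stacklevel=2)
    return out


def theta_series(
    traj: pd.DataFrame, wind_dir: np.ndarray | None = None
) -> np.ndarray:
    """Angle-from-wind series (deg) for a trajectory.

    Uses finite-difference planar velocities; the rotation sense is the
    sign of the net heading rotation over the whole track, so that theta
    increases along the circling direction.  If ``wind_dir`` is None the
    wind direction is estimated with :func:`estimate_wind`.  The first
    value is duplicated so the series has one entry per sample.
    """
    from .environment import compute_theta

    dt = _check_uniform(traj)
    if wind_dir is None:
        wh = estimate_wind(traj).wind_hat
        assert wh is not None
        if np.hypot(*wh) < 1e-9:
            raise ValueError("wind direction undefined: supply wind_dir")
        wind_dir = wh
    x = traj["x"].to_numpy(dtype=float)
    y = traj["y"].to_numpy(dtype=float)
    vx = np.diff(x) / dt
    vy = np.diff(y) / dt
    heading = np.unwrap(np.arctan2(vy, vx))
    sense = 1 if heading[-1] >= heading[0] else -1
    th = np.empty(len(x))
    prev = 0.0
    for i in range(len(vx)):
        try:
            prev = compute_theta(
                np.array([vx[i], vy[i]]), np.asarray(wind_dir, float), sense
            )
        except ValueError:
            pass  # zero horizontal velocity: hold previous value
        th[i + 1] = prev
    th[0] = th[1]
    return th


def _theta_midpoints(
    traj: pd.DataFrame, wind_dir: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Theta evaluated at the forward-difference velocity times t + dt/2.

    Crossing detection needs theta and position on a consistent clock;
    assigning the finite-difference velocity to the interval midpoint
    removes a half-sample lag that would shift every crossing along the
    track.
    """
    from .environment import compute_theta

    dt = _check_uniform(traj)
    if wind_dir is None:
        wh = estimate_wind(traj).wind_hat
        assert wh is not None
        if np.hypot(*wh) < 1e-9:
            raise ValueError("wind direction undefined: supply wind_dir")
        wind_dir = wh
    t = traj["t"].to_numpy(dtype=float)
    x = traj["x"].to_numpy(dtype=float)
    y = traj["y"].to_numpy(dtype=float)
    vx = np.diff(x) / dt
    vy = np.diff(y) / dt
    heading = np.unwrap(np.arctan2(vy, vx))
    sense = 1 if heading[-1] >= heading[0] else -1
    th = np.empty(len(vx))
    prev = 0.0
    for i in range(len(vx)):
        try:
            prev = compute_theta(
                np.array([vx[i], vy[i]]), np.asarray(wind_dir, float), sense
            )
        except ValueError:
            pass
        th[i] = prev
    return 0.5 * (t[:-1] + t[1:]), th


def _crossings(t: np.ndarray, th: np.ndarray, target: str) -> list[float]:
    """Sub-second crossing times of theta through 0 ("B") or +-180 ("A").

    Works on the unwrapped theta series: a crossing of 0 (mod 360) is a
    "B" point (against the wind), a crossing of 180 (mod 360) an "A" point
    (with the wind).  Linear interpolation locates each crossing between
    samples.
    """
    unwrapped = np.degrees(np.unwrap(np.radians(th)))
    offset = 0.0 if target == "B" else 180.0
    times = []
    shifted = (unwrapped - offset) / 360.0
    for i in range(len(shifted) - 1):
        lo, hi = shifted[i], shifted[i + 1]
        if lo == hi:
            continue
        k0 = math.ceil(min(lo, hi))
        k1 = math.floor(max(lo, hi))
        for k in range(k0, k1 + 1):
            frac = (k - lo) / (hi - lo)
            if 0.0 <= frac < 1.0:
                times.append(float(t[i] + frac * (t[i + 1] - t[i])))
    return sorted(times)


def thermalling_diameter(
    traj: pd.DataFrame, wind_dir: np.ndarray | None = None
) -> EstimatorOutput:
    """Local thermalling diameters from interlacing crossing triangles.

    Type-A points are where the track crosses theta = +-180 deg (flying
    with the wind); type-B points where it crosses theta = 0 (against the
    wind).  Time-sorting the crossings gives an alternating sequence; for
    each consecutive ABA triangle the altitude dropped from the middle B
    vertex onto the A-A base — and symmetrically from A in BAB — is one
    local-diameter estimate.
    """
    dt = _check_uniform(traj)
    t = traj["t"].to_numpy(dtype=float)
    x = traj["x"].to_numpy(dtype=float)
    y = traj["y"].to_numpy(dtype=float)
    tm, th = _theta_midpoints(traj, wind_dir)
    a_times = _crossings(tm, th, "A")
    b_times = _crossings(tm, th, "B")
    events = sorted(
        [(tt, "A") for tt in a_times] + [(tt, "B") for tt in b_times]
    )
    # collapse any same-type repeats (noise can produce AA...): keep first
    seq = []
    for tt, kind in events:
        if seq and seq[-1][1] == kind:
            continue
        seq.append((tt, kind))
    out = EstimatorOutput()
    if len(seq) < 3:
        out.warnings.append("fewer than 3 alternating crossings")
        return out

    def pos_at(tt: float) -> np.ndarray:
        return np.array(
            [np.interp(tt, t, x), np.interp(tt, t, y)], dtype=float
        )

    diams = []
    for (t1, k1), (t2, k2), (t3, k3) in zip(seq, seq[1:], seq[2:]):
        p1, p2, p3 = pos_at(t1), pos_at(t2), pos_at(t3)
        base = p3 - p1
        nrm = float(np.hypot(*base))
        if nrm < 2.0:
            # outer points (nearly) coincide: the base direction is noise,
            # use the distance from the middle vertex to their midpoint
            h = float(np.hypot(*(p2 - 0.5 * (p1 + p3))))
        else:
            h = float(abs(base[0] * (p2 - p1)[1] - base[1] * (p2 - p1)[0]) / nrm)
        diams.append(h)
    out.diameters = np.asarray(diams)
    return out


def select_thermalling_segments(
    traj: pd.DataFrame,
    min_duration: float = 100.0,
    min_turns: float = 2.0,
    max_retrograde: float = 0.10,
    min_turn_rate: float = 1.0,
    require_climb: bool = False,
) -> list[pd.DataFrame]:
    """Maximal segments of consistent circling motion.

    A sample is "turning" when the per-second heading change exceeds
    ``min_turn_rate`` deg/s in the segment's dominant direction; a segment
    qualifies when it lasts at least ``min_duration`` seconds, accumulates
    at least ``min_turns`` net turns, and at most ``max_retrograde`` of its
    samples are non-turning or counter-turning.  The selection rule for
    "characteristic, consistent" thermalling in bird data is not uniquely
    defined; this criterion is the package's stand-in and its parameters
    are exposed.
    """
    dt = _check_uniform(traj)
    x = traj["x"].to_numpy(dtype=float)
    y = traj["y"].to_numpy(dtype=float)
    vx = np.diff(x) / dt
    vy = np.diff(y) / dt
    heading = np.unwrap(np.arctan2(vy, vx))
    dpsi = np.degrees(np.diff(heading))  # deg per sample interval
    n = len(dpsi)
    if n == 0:
        return []
    segments: list[tuple[int, int]] = []
    for sense in (+1, -1):
        pro = sense * dpsi > min_turn_rate * dt
        i = 0
        while i < n:
            if not pro[i]:
                i += 1
                continue
            # greedy window: extend while the retrograde fraction allows;
            # keep the last position where the window was still consistent
            bad = 0
            j_best = i
            for j in range(i, n):
                if not pro[j]:
                    bad += 1
                # the window must end on a turning sample, otherwise the
                # retrograde allowance bleeds into adjacent straight flight
                if pro[j] and bad <= max_retrograde * (j - i + 1):
                    j_best = j
                elif j - j_best > 5:  # no recovery within 5 s: stop
                    break
            dur = (j_best - i + 2) * dt
            net = abs(heading[j_best + 1] - heading[i]) / (2 * math.pi)
            if dur >= min_duration and net >= min_turns:
                segments.append((i, j_best + 2))
            i = j_best + 1
    # merge overlapping picks, keep longest non-overlapping set by start
    segments.sort()
    merged: list[tuple[int, int]] = []
    for a, b in segments:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    out = []
    for a, b in merged:
        seg = traj.iloc[a:b].reset_index(drop=True)
        if require_climb and seg["z"].iloc[-1] <= seg["z"].iloc[0]:
            continue
        out.append(seg)
    return out
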