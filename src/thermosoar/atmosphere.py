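"""Thermal updraft profile and the drifting-thermal + horizontal-wind field.

The updraft is a "chimney" thermal: a Lenschow-type vertical amplitude
profile ``w_core(z)``, a Gedeon-type radial shape with a sinking ring, and a
radius ``R(z)`` that grows with altitude.  The whole column drifts downwind
at the uniform horizontal wind speed ``u`` (no centerline leaning), so the
instantaneous center of the thermal at time ``t`` is ``(u*t, 0)``.

All distances are meters, speeds m/s, times seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "ThermalParams",
    "WindConfig",
    "AirVelocity",
    "GustSeries",
    "core_amplitude",
    "thermal_radius",
    "updraft",
    "wind_vector",
]


@dataclass(frozen=True)
class ThermalParams:
    """Characteristic scales of one thermal.

    w_star : characteristic updraft amplitude (m/s), > 0
    z_star : characteristic thermal altitude (m), > 0
    """

    w_star: float = 5.0
    z_star: float = 2000.0

    def __post_init__(self) -> None:
        if not (self.w_star > 0 and self.z_star > 0):
            raise ValueError("w_star and z_star must be positive")


@dataclass(frozen=True)
class WindConfig:
    """Uniform horizontal wind along +x, optionally gusty.

    u : mean horizontal wind speed (m/s), >= 0
    gust_std : std of the Gaussian gust resampling (m/s); 0 disables gusts
    gust_period : gust resampling interval (s)
    """

    u: float = 0.0
    gust_std: float = 0.0
    gust_period: float = 20.0

    def __post_init__(self) -> None:
        if self.u < 0 or self.gust_std < 0 or self.gust_period <= 0:
            raise ValueError("require u >= 0, gust_std >= 0, gust_period > 0")


@dataclass(frozen=True)
class AirVelocity:
    """Local air-velocity components (m/s)."""

    vx: float
    vy: float
    vz: float


def core_amplitude(z, p: ThermalParams):
    """Peak (on-axis) updraft speed at altitude ``z``.

    ``w_core(z) = w* (z/z*)^(1/3) (1 - 1.1 z/z*)``.  Positive below
    ``z = z*/1.1``; taken literally (negative) above that altitude.
    Accepts scalars or arrays; ``z`` must be >= 0.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("altitude z must be >= 0")
    zeta = z / p.z_star
    out = p.w_star * np.cbrt(zeta) * (1.0 - 1.1 * zeta)
    return float(out) if out.ndim == 0 else out


def thermal_radius(z, p: ThermalParams):
    """Thermal radius ``R(z) = 0.08 (z/z*)^(1/3) (1 - z/(4 z*)) z*`` (m)."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("altitude z must be >= 0")
    zeta = z / p.z_star
    out = 0.08 * np.cbrt(zeta) * (1.0 - 0.25 * zeta) * p.z_star
    return float(out) if out.ndim == 0 else out


def updraft(r, z, p: ThermalParams):
    """Vertical air speed at radial distance ``r`` from the thermal axis.

    ``w(r, z) = w_core(z) exp(-(r/R)^2) (1 - (r/R)^2)``: a Gaussian-damped
    core surrounded by a ring of sink for ``r > R(z)``.
    """
    r = np.asarray(r, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("altitude z must be > 0")
    if np.any(r < 0):
        raise ValueError("radial distance r must be >= 0")
    x = (r / thermal_radius(z, p)) ** 2
    out = core_amplitude(z, p) * np.exp(-x) * (1.0 - x)
    return float(out) if out.ndim == 0 else out


def _updraft_scalar(r: float, z: float, p: ThermalParams) -> float:
    """Scalar fast path of :func:`updraft` for the physics inner loop."""
    zeta = z / p.z_star
    cbrt = zeta ** (1.0 / 3.0)
    R = 0.08 * cbrt * (1.0 - 0.25 * zeta) * p.z_star
    x = (r / R) ** 2
    return p.w_star * cbrt * (1.0 - 1.1 * zeta) * math.exp(-x) * (1.0 - x)


class GustSeries:
    """Piecewise-constant gusty wind speed, resampled every ``gust_period`` s.

    Values are drawn from Normal(u, gust_std) truncated at zero, from a
    seeded generator, so a given (config, seed) pair defines one
    reproducible gust realization.  With ``gust_std == 0`` the series is
    identically ``u``.
    """

    def __init__(self, w: WindConfig, rng: Optional[np.random.Generator] = None):
        self.config = w
        self._rng = rng if rng is not None else np.random.default_rng(0)
        self._values: list[float] = []

    def u_at(self, t: float) -> float:
        if self.config.gust_std == 0.0:
            return self.config.u
        idx = int(t // self.config.gust_period)
        while len(self._values) <= idx:
            v = self._rng.normal(self.config.u, self.config.gust_std)
            self._values.append(max(0.0, v))
        return self._values[idx]


def wind_vector(
    x: float,
    y: float,
    z: float,
    t: float,
    w: WindConfig,
    p: ThermalParams,
    gusts: Optional[GustSeries] = None,
) -> AirVelocity:
    """Total air velocity at position ``(x, y, z)`` and time ``t``.

    The horizontal component is the uniform wind ``(u, 0)`` (no altitude
    profile).  The vertical component is the thermal updraft evaluated at
    the distance from the drifted center ``(u*t, 0)``; the center drifts at
    the mean wind speed even when gusts are active, so the thermal keeps a
    coherent vertical structure while the glider feels the gusty wind.
    """
    if z <= 0:
        raise ValueError("altitude z must be > 0")
    u_now = gusts.u_at(t) if gusts is not None else w.u
    r = math.hypot(x - w.u * t, y)
    return AirVelocity(u_now, 0.0, _updraft_scalar(r, z, p))


def thermal_center(t: float, w: WindConfig) -> tuple[float, float]:
    """Horizontal position of the thermal center at time ``t``."""
    return (w.u * t, 0.0)
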