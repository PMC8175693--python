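"""Fishbone surface geometry and its mechanical sampling through a pin matrix.

The stimulus is a raised print: a smooth central strip (the "spine", running
along the y axis) flanked by periodic transverse bars (the "ribs").  A passive
pin matrix rides on top of the moving surface; each pin transmits only the
vertical displacement of the surface underneath its spherical tip.  This
module computes the height field of the pattern and the displacement trace of
a pin while the pattern is scanned underneath it at constant speed.

Units: millimetres for all lengths, milliseconds for time.  A scan speed of
50 mm/s is therefore stored as 0.05 mm/ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FishbonePattern",
    "PinMatrixConfig",
    "ScanConfig",
    "DisplacementTrace",
    "PIN_MATRICES",
    "fishbone_height",
    "edge_distance",
    "pin_displacement",
    "pin_trace",
]


@dataclass(frozen=True)
class FishbonePattern:
    """Geometry of the raised fishbone print.

    Parameters
    ----------
    Lw
        Width of the central spine (mm).  The spine is centred on ``x = 0``
        and runs along the y axis.
    L1
        Rib thickness along y (mm).
    L2
        Gap between consecutive ribs along y (mm).  The rib pattern repeats
        with spatial period ``L1 + L2``.
    h0
        Height of the raised print (mm).  The height field takes only the
        values 0 and ``h0``.
    """

    Lw: float = 4.0
    L1: float = 1.0
    L2: float = 1.0
    h0: float = 0.1

    def __post_init__(self) -> None:
        for name in ("Lw", "L1", "L2", "h0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")

    @property
    def period(self) -> float:
        """Spatial period of the rib pattern along y (mm)."""
        return self.L1 + self.L2


@dataclass(frozen=True)
class PinMatrixConfig:
    """A passive pin matrix: a square lattice of vertically sliding pins.

    ``d1`` is the diameter of the pin head in contact with the fingertip and
    ``d2`` the diameter of the spherical tip in contact with the printed
    surface; ``r1 = d1/2`` and ``rp = d2/2`` are the corresponding radii.
    """

    spacing: float
    d1: float
    d2: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if not (self.d1 > 0 and self.d2 > 0):
            raise ValueError("pin diameters must be positive")

    @property
    def r1(self) -> float:
        """Fingertip-contact radius (mm)."""
        return self.d1 / 2.0

    @property
    def rp(self) -> float:
        """Surface-contact (tip curvature) radius (mm)."""
        return self.d2 / 2.0


#: The three pin matrices used in the experiments.  PM1 has a 1.0 mm pin
#: lattice with 0.8 mm pins; PM2 and PM3 have a 2.0 mm lattice with surface
#: contact diameters of 0.8 and 1.8 mm respectively.  The fingertip-contact
#: diameter d1 of the coarse matrices is 1.8 mm.
PIN_MATRICES: dict[str, PinMatrixConfig] = {
    "PM1": PinMatrixConfig(spacing=1.0, d1=0.8, d2=0.8, name="PM1"),
    "PM2": PinMatrixConfig(spacing=2.0, d1=1.8, d2=0.8, name="PM2"),
    "PM3": PinMatrixConfig(spacing=2.0, d1=1.8, d2=1.8, name="PM3"),
}


@dataclass(frozen=True)
class ScanConfig:
    """Constant-speed scan of the pattern underneath a stationary pin matrix.

    Parameters
    ----------
    V
        Scanning speed in mm/ms (0.05 mm/ms corresponds to 50 mm/s).
    T
        Total simulated time (ms).
    dt
        Sampling / integration step (ms).
    phase0
        Initial y offset of the pattern relative to the pin lattice (mm).
        Offsets are equivalent modulo the rib period.
    """

    V: float = 0.05
    T: float = 800.0
    dt: float = 0.01
    phase0: float = 0.0

    def __post_init__(self) -> None:
        if not self.V > 0:
            raise ValueError("V must be positive")
        if not self.T > 0:
            raise ValueError("T must be positive")
        if not 0 < self.dt <= self.T:
            raise ValueError("dt must satisfy 0 < dt <= T")

    @property
    def n_steps(self) -> int:
        n = round(self.T / self.dt)
        if abs(n * self.dt - self.T) > 1e-9 * max(1.0, self.T):
            raise ValueError(f"T={self.T} is not an integer multiple of dt={self.dt}")
        return n

    def times(self) -> np.ndarray:
        """Sample times 0, dt, ..., T (length ``n_steps + 1``)."""
        return np.arange(self.n_steps + 1) * self.dt


@dataclass(frozen=True)
class DisplacementTrace:
    """Vertical displacement of one pin over a scan."""

    xp: float
    yp: float
    t: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        if self.t.shape != self.h.shape:
            raise ValueError("t and h must have the same shape")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pin_x_mm": self.xp,
                "pin_y_mm": self.yp,
                "t_ms": self.t,
                "h_mm": self.h,
            }
        )


def _as_float_or_array(x: np.ndarray, scalar: bool):
    if scalar:
        return float(x)
    return x


def fishbone_height(x, y, pattern: FishbonePattern):
    """Height of the fishbone pattern at ``(x, y)``.

    Returns ``h0`` on the spine (``|x| < Lw/2``) or on a rib
    (``y mod (L1+L2) < L1``), else 0.  Accepts scalars or arrays.
    """
    scalar = np.isscalar(x) and np.isscalar(y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ymod = np.mod(y, pattern.period)
    on = (np.abs(x) < pattern.Lw / 2.0) | (ymod < pattern.L1)
    h = np.where(on, pattern.h0, 0.0)
    return _as_float_or_array(h, scalar)


def _edge_distance_raw(x, y, pattern: FishbonePattern):
    """Minimum over the four axis-aligned candidate distances to the raised
    pattern.  Valid for points off the pattern; meaningless (negative) on it.
    """
    ymod = np.mod(y, pattern.period)
    ax = np.abs(x)
    # x direction: distances to the near and far spine edges.
    d_spine_near = ax - pattern.Lw / 2.0
    d_spine_far = ax + pattern.Lw / 2.0
    # y direction: distances to the rib behind (edge at ymod = L1) and the
    # rib ahead (edge at ymod = L1 + L2).
    d_rib_down = ymod - pattern.L1
    d_rib_up = pattern.period - ymod
    return np.minimum(
        np.minimum(d_spine_near, d_spine_far), np.minimum(d_rib_down, d_rib_up)
    )


def edge_distance(xp, yp, pattern: FishbonePattern):
    """Distance from an off-pattern pin position to the nearest point of the
    raised pattern, restricted to the four axis-aligned candidates
    ``(xp ± ξ, yp)`` and ``(xp, yp ± ξ)``.

    Raises ``ValueError`` if ``(xp, yp)`` lies on the raised pattern.
    """
    scalar = np.isscalar(xp) and np.isscalar(yp)
    xp = np.asarray(xp, dtype=float)
    yp = np.asarray(yp, dtype=float)
    h = np.asarray(fishbone_height(xp, yp, pattern))
    if np.any(h > 0):
        raise ValueError("edge_distance is defined only off the raised pattern")
    return _as_float_or_array(_edge_distance_raw(xp, yp, pattern), scalar)


def contact_distance(pattern: FishbonePattern, rp: float) -> float:
    """Edge distance ``ξ* = sqrt(2 rp h0 - h0^2)`` within which a spherical
    pin tip of radius ``rp`` still touches the edge of the raised print."""
    return float(np.sqrt(2.0 * rp * pattern.h0 - pattern.h0**2))


def pin_displacement(xp, yp, pattern: FishbonePattern, rp: float):
    """Vertical displacement of a pin with spherical tip radius ``rp``.

    On the raised pattern the pin sits at ``h0``.  Off the pattern it rides
    down the spherical tip profile while the tip still touches a pattern edge
    (``ξ < ξ*``), and rests at 0 beyond that.  Requires ``rp >= h0``;
    otherwise the pin tip cannot ride over the bump and the model does not
    apply.
    """
    if rp < pattern.h0:
        raise ValueError(
            f"pin tip radius rp={rp} must be >= pattern height h0={pattern.h0}"
        )
    scalar = np.isscalar(xp) and np.isscalar(yp)
    xp = np.asarray(xp, dtype=float)
    yp = np.asarray(yp, dtype=float)
    ymod = np.mod(yp, pattern.period)
    on = (np.abs(xp) < pattern.Lw / 2.0) | (ymod < pattern.L1)
    xi = _edge_distance_raw(xp, yp, pattern)
    xi_star = contact_distance(pattern, rp)
    in_contact = xi < xi_star
    # Clip so the sqrt argument stays non-negative where the branch is unused.
    xi_safe = np.minimum(np.abs(xi), rp)
    h_edge = pattern.h0 + np.sqrt(rp**2 - xi_safe**2) - rp
    h = np.where(on, pattern.h0, np.where(in_contact, h_edge, 0.0))
    h = np.clip(h, 0.0, pattern.h0)
    return _as_float_or_array(h, scalar)


def pin_trace(
    pin: tuple[float, float],
    pattern: FishbonePattern,
    scan: ScanConfig,
    rp: float,
) -> DisplacementTrace:
    """Displacement trace of a stationary pin while the pattern moves in +y.

    At time ``t`` the pin at ``(xp, yp)`` samples the pattern at
    ``(xp, yp - V t - phase0)``.
    """
    xp, yp = pin
    t = scan.times()
    y_eff = yp - scan.V * t - scan.phase0
    h = pin_displacement(np.full_like(t, xp), y_eff, pattern, rp)
    return DisplacementTrace(xp=float(xp), yp=float(yp), t=t, h=np.asarray(h))
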