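"""Scar geometry: the rotating ellipsoid and motion constrained to it.

The glial scar is idealized as an ellipsoid of revolution about the vertical
(z) axis.  With horizontal radius r = sqrt((x-x0)² + (y-y0)²) the surface is

    r(z) = ra * sqrt(1 - (z-z0)²/rz²),

and differentiating in time gives the velocity constraint for a particle
moving on the surface,

    Vr = ra² (z0 - z) Vz / (rz² r),   Vx = Vr x/r,  Vy = Vr y/r,

so that a growth cone's full velocity follows from its drawing speed Vz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

__all__ = [
    "ScarGeometry",
    "Placement",
    "surface_radius",
    "surface_normal",
    "meridional_velocity",
    "project_to_surface",
    "place_axons_and_targets",
    "meridian_arc_length",
]

#: fractional pole radius below which the surface constraint is released
POLE_EPS = 0.02


@dataclass(frozen=True)
class ScarGeometry:
    """Ellipsoidal scar: half-axes (μm) and center (μm)."""

    ra: float
    rz: float
    center: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.ra < 0 or self.rz < 0:
            raise ValueError("half-axes ra, rz must be non-negative")
        if len(self.center) != 3:
            raise ValueError("center must be a 3-vector")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def degenerate(self) -> bool:
        return self.ra == 0.0 or self.rz == 0.0

    def residual(self, pos: np.ndarray) -> np.ndarray:
        """Signed residual of the surface equation, (r/ra)² + ((z-z0)/rz)² - 1."""
        pos = np.asarray(pos, dtype=float)
        x0, y0, z0 = self.center
        r2 = (pos[..., 0] - x0) ** 2 + (pos[..., 1] - y0) ** 2
        return r2 / self.ra**2 + (pos[..., 2] - z0) ** 2 / self.rz**2 - 1.0

    def contains(self, pos: np.ndarray) -> np.ndarray:
        """True strictly inside the scar."""
        return self.residual(pos) < 0.0


def surface_radius(z: float | np.ndarray, geom: ScarGeometry) -> float | np.ndarray:
    """Horizontal surface radius at height ``z``; domain |z - z0| <= rz."""
    z = np.asarray(z, dtype=float)
    z0 = geom.center[2]
    zeta = (z - z0) / geom.rz
    if np.any(np.abs(zeta) > 1.0 + 1e-12):
        raise ValueError(f"height z={z} outside the scar's vertical extent")
    r = geom.ra * np.sqrt(np.clip(1.0 - zeta**2, 0.0, None))
    if r.ndim == 0:
        return float(r)
    return r


def surface_normal(pos: np.ndarray, geom: ScarGeometry) -> np.ndarray:
    """Outward unit normal of the ellipsoid at (near-)surface point ``pos``."""
    pos = np.asarray(pos, dtype=float)
    x0, y0, z0 = geom.center
    n = np.stack(
        [
            (pos[..., 0] - x0) / geom.ra**2,
            (pos[..., 1] - y0) / geom.ra**2,
            (pos[..., 2] - z0) / geom.rz**2,
        ],
        axis=-1,
    )
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    return n / norm


def meridional_velocity(
    Vz: float | np.ndarray, pos: np.ndarray, geom: ScarGeometry
) -> np.ndarray:
    """Full velocity (Vx, Vy, Vz) of a surface-bound particle with drawing speed Vz.

    Singular at the poles (r = 0); callers release the constraint near a pole
    (see :data:`POLE_EPS`).
    """
    pos = np.asarray(pos, dtype=float)
    Vz = np.asarray(Vz, dtype=float)
    x0, y0, z0 = geom.center
    dx = pos[..., 0] - x0
    dy = pos[..., 1] - y0
    r = np.hypot(dx, dy)
    if np.any(r <= 0.0):
        raise ValueError("meridional velocity is singular on the axis (r = 0)")
    Vr = geom.ra**2 * (z0 - pos[..., 2]) * Vz / (geom.rz**2 * r)
    return np.stack([Vr * dx / r, Vr * dy / r, Vz * np.ones_like(Vr)], axis=-1)


def project_to_surface(pos: np.ndarray, geom: ScarGeometry) -> np.ndarray:
    """Radially project point(s) onto the scar surface at fixed azimuth and z.

    z is clipped to the scar's vertical extent; the horizontal radius is reset
    to the exact surface radius.  Counteracts the radial drift of explicit
    time stepping; idempotent.
    """
    pos = np.asarray(pos, dtype=float)
    single = pos.ndim == 1
    pts = np.atleast_2d(pos).astype(float).copy()
    x0, y0, z0 = geom.center
    z = np.clip(pts[:, 2], z0 - geom.rz, z0 + geom.rz)
    r_target = np.asarray(surface_radius(z, geom))
    dx = pts[:, 0] - x0
    dy = pts[:, 1] - y0
    r = np.hypot(dx, dy)
    on_axis = r == 0.0
    scale = np.where(on_axis, 0.0, r_target / np.where(on_axis, 1.0, r))
    pts[:, 0] = x0 + dx * scale
    pts[:, 1] = y0 + dy * scale
    # a point on the axis has no azimuth; send it to the nearest pole
    z = np.where(on_axis, z0 + geom.rz * np.where(z >= z0, 1.0, -1.0), z)
    pts[:, 2] = z
    return pts[0] if single else pts


@dataclass(frozen=True)
class Placement:
    """Axon start points and target-cell positions on the scar surface."""

    n_axons: int
    n_targets: int
    axon_latitude: float
    target_latitude: float
    axon_points: np.ndarray = field(repr=False)
    target_points: np.ndarray = field(repr=False)


def _ring(geom: ScarGeometry, latitude: float, n: int, phase: float) -> np.ndarray:
    x0, y0, z0 = geom.center
    z = z0 + latitude * geom.rz
    r = surface_radius(z, geom)
    az = phase + 2.0 * np.pi * np.arange(n) / n
    return np.stack(
        [x0 + r * np.cos(az), y0 + r * np.sin(az), np.full(n, z)], axis=1
    )


def place_axons_and_targets(
    geom: ScarGeometry,
    n_axons: int = 12,
    n_targets: int = 12,
    axon_latitude: float = -0.9,
    target_latitude: float = 0.9,
    axon_phase: float = 0.0,
    target_phase: float = 0.0,
) -> Placement:
    """Place equally spaced rings of axon starts (bottom) and targets (top).

    Latitudes are fractional heights (z - z0)/rz in (-1, 1).
    """
    if n_axons < 1 or n_targets < 1:
        raise ValueError("counts must be >= 1")
    for name, lat in (("axon_latitude", axon_latitude), ("target_latitude", target_latitude)):
        if not -1.0 < lat < 1.0:
            raise ValueError(f"{name} must lie strictly in (-1, 1), got {lat}")
    return Placement(
        n_axons=n_axons,
        n_targets=n_targets,
        axon_latitude=axon_latitude,
        target_latitude=target_latitude,
        axon_points=_ring(geom, axon_latitude, n_axons, axon_phase),
        target_points=_ring(geom, target_latitude, n_targets, target_phase),
    )


def meridian_tangent(pos: np.ndarray, geom: ScarGeometry) -> np.ndarray:
    """Unit tangent(s) along the surface meridian, oriented toward +z.

    In cylindrical coordinates the meridian direction is (dr, dz) ∝ (c, 1)
    with c = ra² (z0 − z) / (rz² r) — the same coefficient as the velocity
    constraint, so meridional velocities are parallel to this tangent.
    """
    pos = np.asarray(pos, dtype=float)
    single = pos.ndim == 1
    pos = np.atleast_2d(pos)
    x0, y0, z0 = geom.center
    dx = pos[:, 0] - x0
    dy = pos[:, 1] - y0
    r = np.hypot(dx, dy)
    if np.any(r <= 0.0):
        raise ValueError("meridian tangent undefined on the axis (r = 0)")
    c = geom.ra**2 * (z0 - pos[:, 2]) / (geom.rz**2 * r)
    t = np.stack([c * dx / r, c * dy / r, np.ones_like(c)], axis=1)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    return t[0] if single else t


def meridian_arc_length(geom: ScarGeometry, lat0: float, lat1: float) -> float:
    """Arc length of the surface meridian between fractional latitudes."""
    z0 = geom.center[2]
    za, zb = sorted((z0 + lat0 * geom.rz, z0 + lat1 * geom.rz))

    def integrand(z: float) -> float:
        zeta = (z - z0) / geom.rz
        s = max(1.0 - zeta**2, 1e-12)
        drdz = -geom.ra * zeta / (geom.rz * math.sqrt(s))
        return math.sqrt(1.0 + drdz**2)

    val, _ = quad(integrand, za, zb, limit=200)
    return float(val)
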