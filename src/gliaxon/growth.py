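"""Chemotactic growth-cone dynamics on the scar surface.

A growth cone is a point particle in the overdamped regime: its velocity is
proportional to the total chemotactic force,

    dr/dt = F/μ,   F = Σi λi p_i,   p_i = ∇ρi |Δr| / ρΣ,   ρΣ = Σi ρi,

with |Δr| the sensing diameter (~the growth-cone width).  p_i is the
dimensionless relative concentration difference across the cone, so the
velocity is invariant under a common rescaling of all concentrations.  The
attractant coefficient λ1 and the promoter coefficient λ3 are positive, the
inhibitor coefficient λ2 negative.

While a cone crawls on the scar the drawing speed Vz = F_z/μ is the free
coordinate and the horizontal velocity follows from the surface constraint
(:func:`gliaxon.geometry.meridional_velocity`); positions are advanced by
explicit Euler steps and re-projected onto the surface.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import geometry
from .fields import FieldState, sample_gradients_and_concentrations

__all__ = [
    "Status",
    "GrowthCone",
    "ForceBreakdown",
    "chemotactic_force",
    "drawing_speed",
    "growth_step",
    "check_connection",
    "check_stall",
    "average_drawing_speed",
]


class Status(str, enum.Enum):
    GROWING = "growing"
    STALLED = "stalled"
    CONNECTED = "connected"


@dataclass
class GrowthCone:
    """State of one regenerating axon's growth cone."""

    index: int
    pos: np.ndarray
    status: Status = Status.GROWING
    connect_time: float | None = None
    z_start: float = 0.0
    path: list = dc_field(default_factory=list)  # (t, x, y, z, Vz) records
    vz_history: list = dc_field(default_factory=list)
    no_signal_streak: int = 0
    slow_streak: int = 0

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float).copy()
        if not self.path:
            self.z_start = float(self.pos[2])
            self.path.append((0.0, *self.pos, 0.0))

    @property
    def net_dz(self) -> float:
        return float(self.pos[2] - self.z_start)


@dataclass(frozen=True)
class ForceBreakdown:
    """Per-factor decomposition of the chemotactic signal at a cone.

    ``p`` holds the dimensionless vectors p_i (rows); ``velocity`` is the
    realized velocity Σi (λi/μ) p_i (μm/s), which is the force divided by the
    viscosity.  ``no_signal`` flags ρΣ = 0 (the cone senses nothing).
    """

    p: np.ndarray
    velocity: np.ndarray
    rho_sigma: float
    no_signal: bool

    @property
    def vz(self) -> float:
        return float(self.velocity[2])


def chemotactic_force(
    gradients: np.ndarray, concentrations: np.ndarray, params
) -> ForceBreakdown:
    """Evaluate the growth law at one cone.

    Parameters
    ----------
    gradients : (3, 3) array, ∇ρi per factor (rows), μM/μm.
    concentrations : (3,) array, ρi at the cone, μM.
    params : :class:`gliaxon.params.ResolvedParams` (uses mob = λi/μ, delta_r).

    ρΣ = 0 yields zero velocity with the ``no_signal`` flag set rather than an
    error: the degenerate case is reachable before the fields are established
    and feeds the stall window.
    """
    gradients = np.asarray(gradients, dtype=float).reshape(3, 3)
    concentrations = np.asarray(concentrations, dtype=float).reshape(3)
    rho_sigma = float(concentrations.sum())
    if rho_sigma <= 0.0:
        return ForceBreakdown(
            p=np.zeros((3, 3)), velocity=np.zeros(3), rho_sigma=rho_sigma, no_signal=True
        )
    p = gradients * params.delta_r / rho_sigma
    velocity = np.asarray(params.mob) @ p
    return ForceBreakdown(p=p, velocity=velocity, rho_sigma=rho_sigma, no_signal=False)


def drawing_speed(force: ForceBreakdown, params=None) -> float:
    """Drawing speed Vz (μm/s): the vertical component of the growth velocity."""
    return force.vz


def growth_step(
    cone: GrowthCone,
    state: FieldState,
    geom: geometry.ScarGeometry,
    params,
    dt_g: float,
    connect_threshold: float | None = None,
    targets: np.ndarray | None = None,
    vz_min: float = 1e-4,
    stall_window: int = 50,
    record: bool = True,
) -> GrowthCone:
    """Advance a single growing cone by one Euler step (in place).

    Samples the fields at the cone, evaluates the growth law, constrains the
    motion to the scar surface (released near the top pole where the
    constraint is singular), re-projects, and updates the status via the
    connection and stall checks.
    """
    if cone.status is not Status.GROWING:
        raise ValueError(f"cone {cone.index} is not growing (status={cone.status.value})")
    grads, concs = sample_gradients_and_concentrations(state, cone.pos[None, :])
    force = chemotactic_force(grads[0], concs[0], params)
    vz = force.vz
    x0, y0, z0 = geom.center
    r = float(np.hypot(cone.pos[0] - x0, cone.pos[1] - y0))
    past_pole = r < geometry.POLE_EPS * geom.ra
    if past_pole:
        velocity = force.velocity  # constraint released near the pole
    else:
        velocity = geometry.meridional_velocity(vz, cone.pos, geom)
    cone.pos = cone.pos + velocity * dt_g
    if not past_pole:
        cone.pos = geometry.project_to_surface(cone.pos, geom)
    t = len(cone.vz_history) * dt_g + dt_g
    cone.vz_history.append(vz)
    if record:
        cone.path.append((t, *cone.pos, vz))
    if force.no_signal:
        cone.no_signal_streak += 1
    else:
        cone.no_signal_streak = 0
    cone.slow_streak = cone.slow_streak + 1 if vz <= vz_min else 0
    if targets is not None:
        threshold = connect_threshold if connect_threshold is not None else params.delta_r
        if check_connection(cone, targets, threshold):
            cone.status = Status.CONNECTED
            cone.connect_time = t
            return cone
    if check_stall(cone, vz_min=vz_min, stall_window=stall_window):
        cone.status = Status.STALLED
    return cone


def check_connection(cone: GrowthCone, targets: np.ndarray, threshold: float) -> bool:
    """True if the cone is strictly within ``threshold`` of any target."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if cone.status is Status.CONNECTED:
        return True
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    d = np.linalg.norm(targets - cone.pos[None, :], axis=1)
    return bool(np.min(d) < threshold)


def check_stall(cone: GrowthCone, vz_min: float = 1e-4, stall_window: int = 50) -> bool:
    """True if the cone has been (effectively) immobile for a full window.

    Stalled iff Vz <= vz_min for ``stall_window`` consecutive steps, or the
    no-signal condition has persisted that long.  Absorbing: a stalled cone
    never resumes.
    """
    if cone.status is Status.STALLED:
        return True
    return cone.slow_streak >= stall_window or cone.no_signal_streak >= stall_window


def average_drawing_speed(cones, t_end: float) -> float:
    """Population-average drawing speed (μm/s).

    Per cone: net vertical displacement divided by its connection time if it
    connected, else by ``t_end``.  The primary growth-rate metric of the
    sweeps.
    """
    cones = list(cones)
    if not cones:
        raise ValueError("no cones to average over")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    speeds = []
    for c in cones:
        T = c.connect_time if (c.status is Status.CONNECTED and c.connect_time) else t_end
        speeds.append(c.net_dz / T)
    return float(np.mean(speeds))
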