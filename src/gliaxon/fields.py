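"""Reaction-diffusion guidance fields solved with a D3Q7 lattice Boltzmann scheme.

Each guidance factor obeys

    ∂ρi/∂t = Di ∇²ρi − k-i ρi + Σ_sources σ δ(r − r_s),

with the attractant released at fixed target cells and the inhibitor/promoter
released at the (moving) growth cones, where the release rates are coupled to
the local attractant concentration through the receptor-ligand bound fraction
R_L = ρ1/(Kd + ρ1):  σ2 = σ20 (1 − R_L),  σ3 = σ30 R_L.

Numerics
--------
Pure diffusion needs no advection, so the cheapest 3D stencil suffices: D3Q7
BGK with rest weight 1/4 and link weight 1/8 (lattice sound speed cs² = 1/4),
giving D = cs² (τ − 1/2) Δx²/Δt.  Decay is a multiplicative post-stream sink
(so a decay-only field follows (1 − kΔt)ⁿ exactly) and point sources deposit
σΔt of concentration at their host node (nearest) or spread trilinearly over
the 8 surrounding nodes.  The scar interior and the six domain faces are
zero-flux via half-way bounce-back, which conserves mass to round-off.

A point source σ at one node corresponds to a continuum source of strength
Q = σ Δx³ (concentration·volume per time); the steady screened Green's
function ρ(d) = Q e^{−d√(k/D)} / (4πDd) is provided as the validation oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import ScarGeometry

__all__ = [
    "ATTRACTANT",
    "INHIBITOR",
    "PROMOTER",
    "Lattice",
    "FieldState",
    "SourceSet",
    "build_lattice",
    "receptor_ligand_fraction",
    "release_rates",
    "analytic_point_source",
    "lbm_step",
    "run_to_quasi_steady",
    "seed_attractant_analytic",
    "sample_fields",
    "sample_gradient",
]

ATTRACTANT, INHIBITOR, PROMOTER = 0, 1, 2

# D3Q7: rest + the six axis links.
_C = np.array(
    [[0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=int,
)
_W = np.array([0.25, 0.125, 0.125, 0.125, 0.125, 0.125, 0.125])
_OPP = np.array([0, 2, 1, 4, 3, 6, 5])
CS2 = 0.25

# 8 cell-corner offsets for trilinear interpolation/deposition.
_CORNERS = np.array(
    [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=int
)


@dataclass(frozen=True)
class Lattice:
    """Cubic lattice of node-centered cells covering [0, L]³.

    Node (i, j, k) sits at ((i+½)Δx, (j+½)Δx, (k+½)Δx).  ``solid`` marks the
    scar interior (zero concentration, bounce-back walls).
    """

    L: float
    dx: float
    n: int
    solid: np.ndarray = field(repr=False)
    geom: ScarGeometry | None = None

    @property
    def axis(self) -> np.ndarray:
        return (np.arange(self.n) + 0.5) * self.dx

    @property
    def n_fluid(self) -> int:
        return int(self.n**3 - self.solid.sum())

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return np.all((pts >= 0.0) & (pts <= self.L), axis=1)


def build_lattice(L: float, dx: float, geom: ScarGeometry | None = None) -> Lattice:
    """Build the lattice and scar-interior obstacle mask.

    ``L/dx`` must be integral; node centers strictly inside the ellipsoid are
    marked solid.
    """
    if dx <= 0:
        raise ValueError("dx must be positive")
    n_f = L / dx
    n = round(n_f)
    if n < 2 or abs(n_f - n) > 1e-9 * max(1.0, n_f):
        raise ValueError(f"L/dx = {n_f} is not an integer >= 2")
    if geom is None or geom.degenerate:
        solid = np.zeros((n, n, n), dtype=bool)
    else:
        ax = (np.arange(n) + 0.5) * dx
        x0, y0, z0 = geom.center
        xx = ((ax - x0) ** 2)[:, None, None]
        yy = ((ax - y0) ** 2)[None, :, None]
        zz = (((ax - z0) / geom.rz) ** 2)[None, None, :]
        solid = (xx + yy) / geom.ra**2 + zz < 1.0
    return Lattice(L=float(L), dx=float(dx), n=n, solid=solid, geom=geom)


def receptor_ligand_fraction(rho1: float | np.ndarray, Kd: float) -> float | np.ndarray:
    """Bound receptor fraction R_L = ρ1/(Kd + ρ1); in [0, 1)."""
    if Kd <= 0:
        raise ValueError("Kd must be positive")
    rho1 = np.asarray(rho1, dtype=float)
    if np.any(rho1 < 0):
        raise ValueError("attractant concentration must be non-negative")
    out = rho1 / (Kd + rho1)
    return float(out) if out.ndim == 0 else out


def release_rates(
    rho1: float | np.ndarray, sigma20: float, sigma30: float, Kd: float
) -> tuple[np.ndarray, np.ndarray]:
    """Inhibitor/promoter release rates σ2 = σ20(1−R_L), σ3 = σ30·R_L."""
    RL = np.asarray(receptor_ligand_fraction(rho1, Kd))
    return sigma20 * (1.0 - RL), sigma30 * RL


def analytic_point_source(d: float | np.ndarray, Q: float, D: float, k: float) -> float | np.ndarray:
    """Steady screened point-source solution ρ(d) = Q e^{−d√(k/D)}/(4πDd).

    ``Q`` is the source strength in concentration·volume per time (for a
    nodal rate σ, Q = σΔx³); ``k >= 0`` (k = 0 gives the plain Green's
    function).  Singular at d = 0.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance must be positive (the source point is singular)")
    if D <= 0 or k < 0:
        raise ValueError("need D > 0 and k >= 0")
    out = Q * np.exp(-d * math.sqrt(k / D)) / (4.0 * math.pi * D * d)
    return float(out) if out.ndim == 0 else out


@dataclass
class SourceSet:
    """Fixed target-cell sources and mobile growth-cone sources.

    ``spreading`` selects the delta-function discretization: "trilinear"
    spreads each source over the 8 surrounding nodes (default; the self-field
    then moves smoothly with a moving source), "nearest" deposits on the host
    node.  Weights falling on solid nodes are renormalized onto the fluid
    nodes of the cell.
    """

    targets: np.ndarray
    cones: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    spreading: str = "trilinear"

    def __post_init__(self) -> None:
        self.targets = np.atleast_2d(np.asarray(self.targets, dtype=float))
        self.cones = np.asarray(self.cones, dtype=float).reshape(-1, 3)
        if self.spreading not in ("trilinear", "nearest"):
            raise ValueError(f"unknown spreading mode {self.spreading!r}")


class FieldState:
    """Concentration lattices + LBM populations for the three factors.

    The shared time step is fixed at construction from the largest diffusion
    coefficient so that every factor's relaxation time τi = ½ + DiΔt/(cs²Δx²)
    stays in (½, 2]; ``tau_max`` is the τ given to the fastest factor
    (defaults to 1, which also keeps populations non-negative for the slower
    factors).
    """

    def __init__(
        self,
        lattice: Lattice,
        params,
        tau_max: float = 1.0,
        dt: float | None = None,
    ) -> None:
        D = np.asarray(params.D, dtype=float)
        k = np.asarray(params.k, dtype=float)
        if dt is None:
            if not 0.5 < tau_max <= 2.0:
                raise ValueError(f"tau_max must lie in (1/2, 2], got {tau_max}")
            dt = CS2 * (tau_max - 0.5) * lattice.dx**2 / D.max()
        tau = 0.5 + D * dt / (CS2 * lattice.dx**2)
        if np.any(tau <= 0.5) or np.any(tau > 2.0):
            raise ValueError(
                f"relaxation times {tau} outside the stable range (1/2, 2]; "
                "reduce dt or the spread of diffusion coefficients"
            )
        if np.any(k * dt >= 1.0):
            raise ValueError(f"decay per step k*dt = {k * dt} must stay below 1")
        self.lattice = lattice
        self.params = params
        self.dt = float(dt)
        self.tau = tau
        self.t = 0.0
        n = lattice.n
        self.f = np.zeros((3, 7, n, n, n))
        self._rho = np.zeros((3, n, n, n))

    def rho(self, i: int) -> np.ndarray:
        """Concentration lattice of factor ``i`` (μM)."""
        return self._rho[i]

    def set_rho(self, i: int, rho: np.ndarray) -> None:
        """Impose a concentration field (populations set to equilibrium)."""
        rho = np.asarray(rho, dtype=float)
        rho = np.where(self.lattice.solid, 0.0, rho)
        self.f[i] = _W[:, None, None, None] * rho[None]
        self._rho[i] = self.f[i].sum(axis=0)

    def total_mass(self, i: int) -> float:
        """Total amount of factor i in concentration·volume units."""
        return float(self._rho[i].sum()) * self.lattice.dx**3

    def copy(self) -> "FieldState":
        new = FieldState.__new__(FieldState)
        new.lattice = self.lattice
        new.params = self.params
        new.dt = self.dt
        new.tau = self.tau.copy()
        new.t = self.t
        new.f = self.f.copy()
        new._rho = self._rho.copy()
        return new


def _stream(f: np.ndarray, solid: np.ndarray) -> np.ndarray:
    """Stream populations with half-way bounce-back at solids and walls."""
    out = np.empty_like(f)
    out[0] = f[0]
    for i in range(1, 7):
        c = _C[i]
        g = np.roll(f[i], shift=tuple(c), axis=(0, 1, 2))
        # arrivals whose upwind neighbor is solid are replaced by the node's
        # own post-collision opposite population (half-way bounce-back)
        upwind_solid = np.roll(solid, shift=tuple(c), axis=(0, 1, 2))
        if upwind_solid.any():
            g[upwind_solid] = f[_OPP[i]][upwind_solid]
        # domain walls: undo the periodic wrap of np.roll on the entry face
        axis = int(np.nonzero(c)[0][0])
        face = 0 if c[axis] > 0 else -1
        sl = [slice(None)] * 3
        sl[axis] = face
        g[tuple(sl)] = f[_OPP[i]][tuple(sl)]
        out[i] = g
    out[:, solid] = 0.0
    return out


def _interp_weights(
    lattice: Lattice, pts: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flat corner indices and solid-masked trilinear weights for points.

    Returns (idx (m,8), w (m,8), wsum (m,)); weights on solid nodes are
    zeroed and *not* renormalized — callers divide by wsum (interpolation) or
    renormalize (deposition).
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    if not lattice.contains(pts).all():
        raise ValueError("point(s) outside the simulation domain")
    n = lattice.n
    g = pts / lattice.dx - 0.5
    i0 = np.clip(np.floor(g).astype(int), 0, n - 2)
    fr = np.clip(g - i0, 0.0, 1.0)
    corners = i0[:, None, :] + _CORNERS[None, :, :]  # (m, 8, 3)
    w = np.ones((pts.shape[0], 8))
    for ax in range(3):
        t = fr[:, ax][:, None]
        cw = np.where(_CORNERS[None, :, ax] == 1, t, 1.0 - t)
        w *= cw
    idx = (corners[..., 0] * n + corners[..., 1]) * n + corners[..., 2]
    fluid = ~lattice.solid.ravel()[idx]
    w = w * fluid
    return idx, w, w.sum(axis=1)


def _deposit(
    f: np.ndarray,
    lattice: Lattice,
    pts: np.ndarray,
    amounts: np.ndarray,
    spreading: str,
) -> None:
    """Add ``amounts`` (μM of concentration) at points, spread per mode."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    amounts = np.broadcast_to(np.asarray(amounts, dtype=float), (pts.shape[0],))
    if pts.shape[0] == 0:
        return
    idx, w, wsum = _interp_weights(lattice, pts)
    if np.any(wsum <= 0):
        raise ValueError("source position has no fluid node in its cell (inside obstacle?)")
    if spreading == "nearest":
        best = np.argmax(w, axis=1)
        node_idx = idx[np.arange(len(best)), best]
        node_amt = amounts
    else:
        node_idx = idx.ravel()
        node_amt = (w / wsum[:, None] * amounts[:, None]).ravel()
    flat = f.reshape(7, -1)
    add = np.zeros(flat.shape[1])
    np.add.at(add, node_idx, node_amt)
    nz = np.nonzero(add)[0]
    flat[:, nz] += _W[:, None] * add[nz][None, :]


def lbm_step(
    state: FieldState,
    sources: SourceSet,
    params=None,
    factors: Sequence[int] = (0, 1, 2),
) -> FieldState:
    """Advance the listed factors by one collide-stream-react step (in place).

    Order per factor: BGK collision, streaming with bounce-back, multiplicative
    decay, source deposition.  Mobile (growth-cone) release rates are
    re-evaluated from the current attractant field before depositing.
    Returns ``state`` for convenience.
    """
    params = params or state.params
    lat = state.lattice
    dt = state.dt
    have_cones = sources.cones.shape[0] > 0 and (
        INHIBITOR in factors or PROMOTER in factors
    )
    if have_cones:
        rho1_at = sample_fields(state, sources.cones, (ATTRACTANT,))[0]
        s2, s3 = release_rates(
            np.clip(rho1_at, 0.0, None), params.sigma20, params.sigma30, params.Kd
        )
    for i in factors:
        fi = state.f[i]
        rho = state._rho[i]
        omega = 1.0 / state.tau[i]
        # collision toward feq = w * rho
        fi *= 1.0 - omega
        fi += (omega * _W)[:, None, None, None] * rho[None]
        fi = _stream(fi, lat.solid)
        fi *= 1.0 - params.k[i] * dt
        if i == ATTRACTANT and sources.targets.shape[0] > 0:
            _deposit(
                fi,
                lat,
                sources.targets,
                np.full(sources.targets.shape[0], params.sigma1 * dt),
                sources.spreading,
            )
        elif i == INHIBITOR and have_cones:
            _deposit(fi, lat, sources.cones, s2 * dt, sources.spreading)
        elif i == PROMOTER and have_cones:
            _deposit(fi, lat, sources.cones, s3 * dt, sources.spreading)
        state.f[i] = fi
        state._rho[i] = fi.sum(axis=0)
    state.t += dt
    return state


def run_to_quasi_steady(
    state: FieldState,
    sources: SourceSet,
    params=None,
    tol: float = 1e-6,
    factors: Sequence[int] = (ATTRACTANT,),
    max_steps: int = 50_000,
    min_steps: int = 1,
) -> dict:
    """Step the listed factors until the total mass is quasi-stationary.

    Converged when the relative change of total mass (of the first listed
    factor) per step drops below ``tol`` after at least ``min_steps``.
    Returns an info dict; on hitting ``max_steps`` a warning is issued and
    ``converged`` is False (the partial state remains usable).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    params = params or state.params
    lead = factors[0]
    mass_prev = state.total_mass(lead)
    history = [mass_prev]
    steps = 0
    converged = False
    while steps < max_steps:
        lbm_step(state, sources, params, factors=factors)
        steps += 1
        mass = state.total_mass(lead)
        history.append(mass)
        denom = max(mass, 1e-300)
        if steps >= min_steps and abs(mass - mass_prev) / denom < tol:
            converged = True
            break
        mass_prev = mass
    if not converged:
        warnings.warn(
            f"quasi-steady burn-in did not converge within {max_steps} steps",
            RuntimeWarning,
            stacklevel=2,
        )
    return {"converged": converged, "steps": steps, "mass_history": np.array(history)}


def seed_attractant_analytic(
    state: FieldState, sources: SourceSet, params=None
) -> None:
    """Initialize ρ1 with superposed screened point-source solutions.

    Ignores the obstacle (field zeroed inside it); a short LBM relaxation
    afterwards establishes the diffusion shadow of the scar.
    """
    params = params or state.params
    lat = state.lattice
    ax = lat.axis
    X = ax[:, None, None]
    Y = ax[None, :, None]
    Z = ax[None, None, :]
    Q = params.sigma1 * lat.dx**3
    rho = np.zeros((lat.n,) * 3)
    for tx, ty, tz in np.atleast_2d(sources.targets):
        d = np.sqrt((X - tx) ** 2 + (Y - ty) ** 2 + (Z - tz) ** 2)
        d = np.maximum(d, 0.5 * lat.dx)
        rho += analytic_point_source(d, Q, params.D1, params.k1)
    state.set_rho(ATTRACTANT, rho)


def sample_fields(
    state: FieldState, pts: np.ndarray, factors: Sequence[int] = (0, 1, 2)
) -> np.ndarray:
    """Solid-masked trilinear interpolation of factor fields at points.

    Returns an array of shape (len(factors), m).  Cells whose corners are all
    solid interpolate to 0.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    idx, w, wsum = _interp_weights(state.lattice, pts)
    denom = np.maximum(wsum, 1e-300)
    out = np.empty((len(factors), pts.shape[0]))
    for j, i in enumerate(factors):
        flat = state._rho[i].ravel()
        out[j] = (flat[idx] * w).sum(axis=1) / denom
    return out


def sample_gradient(state: FieldState, i: int, pos: np.ndarray) -> np.ndarray:
    """Central-difference gradient of factor ``i`` at a single point.

    Stencil points ``pos ± Δx ê`` are evaluated by solid-masked trilinear
    interpolation; a stencil arm falling (mostly) inside the obstacle is
    dropped and a one-sided difference used instead.
    """
    grads, _ = sample_gradients_and_concentrations(state, np.atleast_2d(pos), (i,))
    return grads[0, 0]


def sample_gradients_and_concentrations(
    state: FieldState, pts: np.ndarray, factors: Sequence[int] = (0, 1, 2)
) -> tuple[np.ndarray, np.ndarray]:
    """Batched gradients and concentrations for many points.

    Returns (grads, concs) with shapes (m, len(factors), 3) and
    (m, len(factors)).  Gradients use the ±Δx central-difference stencil with
    solid-aware one-sided fallback.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    m = pts.shape[0]
    lat = state.lattice
    dx = lat.dx
    offsets = np.vstack([np.zeros(3), np.eye(3) * dx, -np.eye(3) * dx])  # (7,3)
    stencil = (pts[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    # stay inside the domain: clamp stencil points (cones live well inside)
    stencil = np.clip(stencil, 0.0, lat.L)
    idx, w, wsum = _interp_weights(lat, stencil)
    denom = np.maximum(wsum, 1e-300)
    valid = (wsum > 0.5).reshape(m, 7)
    grads = np.zeros((m, len(factors), 3))
    concs = np.zeros((m, len(factors)))
    for j, i in enumerate(factors):
        flat = state._rho[i].ravel()
        vals = ((flat[idx] * w).sum(axis=1) / denom).reshape(m, 7)
        concs[:, j] = vals[:, 0]
        for ax in range(3):
            vp, vm = vals[:, 1 + ax], vals[:, 4 + ax]
            okp, okm = valid[:, 1 + ax], valid[:, 4 + ax]
            central = (vp - vm) / (2.0 * dx)
            fwd = (vp - vals[:, 0]) / dx
            bwd = (vals[:, 0] - vm) / dx
            g = np.where(okp & okm, central, np.where(okp, fwd, np.where(okm, bwd, 0.0)))
            grads[:, j, ax] = g
    return grads, concs
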