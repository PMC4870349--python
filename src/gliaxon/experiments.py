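"""Scenario driver and the two computational studies.

A scenario couples the three-field reaction-diffusion solve to the
surface-constrained growth of a cluster of regenerating axons:

1. the attractant field released by the target cells is burned in to quasi
   steady state (it does not depend on the cones);
2. the growth loop advances every growing cone by explicit Euler steps,
   sampling gradients by central differences around each cone; the
   cone-released inhibitor/promoter fields are re-relaxed to their (fast)
   quasi-steady state every ``couple_every`` growth steps, and only when the
   cones have actually moved a meaningful fraction of a lattice cell;
3. the run terminates when every cone has connected or stalled, or at t_max.

The two studies are the inhibitor-ratio sweep (η2 ∈ {3..7}%, spherical scar
of radius 0.26 L) and the scar size/shape sweep (five ellipsoid cases at
η2 = η3 = 3%).

Presets
-------
``full_preset`` is the physical configuration (L = 6720 μm, attractant
diffusion distance 1000 μm, 96³ lattice).  ``desk_preset`` is a geometrically
similar shrink by 4 (all lengths and the diffusion distance divided by 4) on
a 64³ lattice, with the attractant release rate rescaled so the concentration
scale relative to Kd of the full-scale reference discretization is preserved
(Q/(D·distance) invariant).  Dimensionless shape ratios (ra/L, Δr/λ_diff,
η's, λ ratios) are identical, so the desk runs exercise the same regime at a
fraction of the cost.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .fields import (
    ATTRACTANT,
    INHIBITOR,
    PROMOTER,
    FieldState,
    SourceSet,
    build_lattice,
    lbm_step,
    run_to_quasi_steady,
    sample_fields,
    sample_gradients_and_concentrations,
    seed_attractant_analytic,
)
from .geometry import (
    POLE_EPS,
    ScarGeometry,
    meridian_arc_length,
    meridian_tangent,
    place_axons_and_targets,
    project_to_surface,
    surface_normal,
)
from .growth import GrowthCone, Status, average_drawing_speed
from .params import BaseConfig, ResolvedParams, base_config_from_mapping, resolve_parameters

__all__ = [
    "SCAR_CASES",
    "ScenarioConfig",
    "ScenarioResult",
    "SweepResult",
    "desk_preset",
    "full_preset",
    "run_scenario",
    "run_eta2_sweep",
    "run_scar_sweep",
    "clear_caches",
]

#: the five scar geometries of the size/shape study, (ra/L, rz/L)
SCAR_CASES: dict[int, tuple[float, float]] = {
    1: (0.26, 0.20),
    2: (0.20, 0.26),
    3: (0.26, 0.26),
    4: (0.32, 0.26),
    5: (0.26, 0.32),
}

#: low end of the physiological axon growth-rate band (μm/s), used to size t_max
GROWTH_SPEED_FLOOR = 0.01

#: full-scale reference lattice spacing (μm) that fixes the nodal source scale
REF_DX_FULL = 70.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete, serializable description of one simulation scenario."""

    base: BaseConfig = dc_field(default_factory=BaseConfig)
    label: str = "scenario"
    ra_frac: float = 0.26
    rz_frac: float = 0.26
    n_axons: int = 12
    n_targets: int = 12
    axon_latitude: float = -0.9
    target_latitude: float = 0.9
    n_side: int = 96
    obstacle: bool = True
    tau_max: float = 1.0
    spreading: str = "trilinear"
    init: str = "analytic"
    burnin_tol: float = 1e-6
    burnin_min_steps: int = 1000
    burnin_max_steps: int = 20000
    dt_growth: float = 1.0
    couple_every: int = 200
    relax_steps: int | None = None
    # refresh the cone-released fields once any cone has moved this fraction
    # of a cell since the last refresh: the quasi-static self-field must track
    # the cone closely, or a trailing spike exerts a spurious tangential push
    refresh_min_move: float = 0.02
    t_max: float | None = None
    force_projection: str = "tangent"
    connect_threshold: float | None = None
    vz_min: float = 1e-4
    stall_window: int = 50
    history_every: int = 50
    keep_fields: bool = False

    def __post_init__(self) -> None:
        if self.ra_frac >= 0.5 or self.rz_frac >= 0.5:
            raise ValueError("scar half-axes must fit inside the cubic domain (fraction < 0.5)")
        if self.ra_frac <= 0 or self.rz_frac <= 0:
            raise ValueError("scar half-axes must be positive")
        if self.init not in ("analytic", "zero"):
            raise ValueError(f"unknown init mode {self.init!r}")
        if self.force_projection not in ("tangent", "vertical"):
            raise ValueError(f"unknown force projection {self.force_projection!r}")
        if self.dt_growth <= 0 or (self.t_max is not None and self.t_max <= 0):
            raise ValueError("time steps and t_max must be positive")

    # -- derived pieces -------------------------------------------------
    def geometry(self) -> ScarGeometry:
        L = self.base.L
        return ScarGeometry(
            ra=self.ra_frac * L, rz=self.rz_frac * L, center=(L / 2, L / 2, L / 2)
        )

    def resolved(self) -> ResolvedParams:
        return resolve_parameters(self.base)

    def effective_t_max(self) -> float:
        if self.t_max is not None:
            return self.t_max
        arc = meridian_arc_length(
            self.geometry(), self.axon_latitude, self.target_latitude
        )
        return 2.0 * arc / GROWTH_SPEED_FLOOR

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["base"] = self.base.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["base"] = base_config_from_mapping(d.get("base", {}))
        return cls(**d)

    def cache_key(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class ScenarioResult:
    """Outcome of one scenario run."""

    config: ScenarioConfig
    n_connected: int
    n_stalled: int
    vz_avg: float
    connect_times: np.ndarray
    statuses: list[str]
    t_end: float
    cones: list[GrowthCone]
    representative: int
    traj_t: np.ndarray
    traj_pos: np.ndarray  # (n_records, n_axons, 3)
    traj_vz: np.ndarray  # (n_records, n_axons)
    traj_status: np.ndarray  # (n_records, n_axons) int codes 0/1/2
    provenance: dict
    flags: dict
    fields: np.ndarray | None = None  # (3, n, n, n) final concentrations
    lattice: object | None = None

    @property
    def flagged(self) -> bool:
        return not all(self.flags.values())

    @property
    def label(self) -> str:
        return self.config.label

    def rep_history(self) -> np.ndarray:
        """(t, Vz) time history of the representative axon."""
        return np.column_stack([self.traj_t, self.traj_vz[:, self.representative]])


@dataclass
class SweepResult:
    """Ordered collection of scenario results with a tabular view."""

    rows: list[ScenarioResult]

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "label": r.label,
                    "eta2": r.config.base.eta2,
                    "eta3": r.config.base.eta3,
                    "ra_frac": r.config.ra_frac,
                    "rz_frac": r.config.rz_frac,
                    "vz_ave": r.vz_avg,
                    "n_connected": r.n_connected,
                    "n_stalled": r.n_stalled,
                    "t_end": r.t_end,
                    "flagged": r.flagged,
                }
            )
        return pd.DataFrame.from_records(recs)


# ----------------------------------------------------------------------
# presets


def full_preset(
    eta2: float = 0.03,
    eta3: float = 0.03,
    ra_frac: float = 0.26,
    rz_frac: float = 0.26,
    n_side: int = 96,
    label: str | None = None,
    **overrides,
) -> ScenarioConfig:
    """Full physical scale: L = 6720 μm, λ_diff = 1000 μm, 96³ lattice."""
    base = BaseConfig(eta2=eta2, eta3=eta3)
    if label is None:
        label = f"full_eta2={eta2:g}_ra={ra_frac:g}_rz={rz_frac:g}"
    return ScenarioConfig(
        base=base, label=label, ra_frac=ra_frac, rz_frac=rz_frac, n_side=n_side, **overrides
    )


def desk_preset(
    eta2: float = 0.03,
    eta3: float = 0.03,
    ra_frac: float = 0.26,
    rz_frac: float = 0.26,
    n_side: int = 64,
    shrink: float = 4.0,
    label: str | None = None,
    **overrides,
) -> ScenarioConfig:
    """Geometrically similar shrink of the full configuration (factor 4).

    All lengths, the diffusion distance, and the sensing diameter shrink by
    ``shrink``; σ1 is rescaled so the attractant concentration scale relative
    to Kd matches the full-scale reference discretization (the nodal source
    strength Q = σΔx³ scales with 1/shrink, as does the source-cone distance).
    """
    L = 6720.0 / shrink
    dx = L / n_side
    q_ref = 6.0e-3 * REF_DX_FULL**3  # full-scale nodal source strength
    sigma1 = q_ref / (shrink * dx**3)
    base = BaseConfig(
        L=L,
        lambda_diff=1000.0 / shrink,
        delta_r=20.0 / shrink,
        sigma1=sigma1,
        eta2=eta2,
        eta3=eta3,
    )
    if label is None:
        label = f"desk_eta2={eta2:g}_ra={ra_frac:g}_rz={rz_frac:g}"
    return ScenarioConfig(
        base=base, label=label, ra_frac=ra_frac, rz_frac=rz_frac, n_side=n_side, **overrides
    )


# ----------------------------------------------------------------------
# caches

_BURNIN_CACHE: dict[str, tuple[np.ndarray, dict]] = {}
_SCENARIO_CACHE: dict[str, ScenarioResult] = {}


def clear_caches() -> None:
    _BURNIN_CACHE.clear()
    _SCENARIO_CACHE.clear()


def _burnin_key(cfg: ScenarioConfig) -> str:
    d = cfg.to_dict()
    # fields that the attractant burn-in actually depends on
    keep = {
        "base",
        "ra_frac",
        "rz_frac",
        "n_targets",
        "target_latitude",
        "n_side",
        "obstacle",
        "tau_max",
        "spreading",
        "init",
        "burnin_tol",
        "burnin_min_steps",
        "burnin_max_steps",
    }
    d = {k: v for k, v in d.items() if k in keep}
    # the attractant field is independent of the inhibitor/promoter ratios
    d["base"] = {k: v for k, v in d["base"].items() if k not in ("eta2", "eta3")}
    return json.dumps(d, sort_keys=True)


def _attractant_field(cfg, params, lattice, placement) -> tuple[np.ndarray, dict]:
    key = _burnin_key(cfg)
    if key in _BURNIN_CACHE:
        rho1, info = _BURNIN_CACHE[key]
        return rho1, info
    state = FieldState(lattice, params, tau_max=cfg.tau_max)
    sources = SourceSet(targets=placement.target_points, spreading=cfg.spreading)
    if cfg.init == "analytic":
        seed_attractant_analytic(state, sources, params)
    info = run_to_quasi_steady(
        state,
        sources,
        params,
        tol=cfg.burnin_tol,
        factors=(ATTRACTANT,),
        max_steps=cfg.burnin_max_steps,
        min_steps=cfg.burnin_min_steps,
    )
    info = {"converged": info["converged"], "steps": info["steps"]}
    rho1 = state.rho(ATTRACTANT).copy()
    _BURNIN_CACHE[key] = (rho1, info)
    return rho1, info


# ----------------------------------------------------------------------
# scenario runner

_GROWING, _STALLED, _CONNECTED = 0, 1, 2
_STATUS_NAMES = {_GROWING: "growing", _STALLED: "stalled", _CONNECTED: "connected"}


def run_scenario(cfg: ScenarioConfig, cache: bool = True) -> ScenarioResult:
    """Run one scenario to completion.

    Deterministic: identical configurations give bit-identical results.  With
    ``cache=True`` (default) results and attractant burn-ins are memoized per
    process; cached results must be treated as read-only.
    """
    key = cfg.cache_key()
    if cache and key in _SCENARIO_CACHE:
        return _SCENARIO_CACHE[key]

    params = cfg.resolved()
    geom = cfg.geometry()
    L = params.L
    lattice = build_lattice(L, L / cfg.n_side, geom if cfg.obstacle else None)
    placement = place_axons_and_targets(
        geom,
        n_axons=cfg.n_axons,
        n_targets=cfg.n_targets,
        axon_latitude=cfg.axon_latitude,
        target_latitude=cfg.target_latitude,
    )
    rho1, burn_info = _attractant_field(cfg, params, lattice, placement)

    state = FieldState(lattice, params, tau_max=cfg.tau_max)
    state.set_rho(ATTRACTANT, rho1)
    relax = cfg.relax_steps
    if relax is None:
        relax = int(np.clip(math.ceil(4.0 / (params.k2 * state.dt)), 4, 60))

    pos = placement.axon_points.copy()

    def body_center(p: np.ndarray) -> np.ndarray:
        # the cone's body (release and sensing volume) sits half a cell off
        # the substrate along the outward normal
        return p + 0.5 * lattice.dx * surface_normal(p, geom)

    sources = SourceSet(
        targets=placement.target_points, cones=body_center(pos), spreading=cfg.spreading
    )
    cones_release = params.sigma20 > 0.0 or params.sigma30 > 0.0
    if cones_release:
        for _ in range(2 * relax):  # initial inhibitor/promoter spin-up
            lbm_step(state, sources, params, factors=(INHIBITOR, PROMOTER))

    NA = cfg.n_axons
    mob = np.asarray(params.mob)
    x0, y0, z0 = geom.center
    t_max = cfg.effective_t_max()
    n_steps_max = int(math.ceil(t_max / cfg.dt_growth))
    # connection radius: the sensing diameter, floored at half a lattice cell
    # (the discrete field cannot localize a target more sharply than that)
    thr = (
        cfg.connect_threshold
        if cfg.connect_threshold is not None
        else max(params.delta_r, 0.5 * lattice.dx)
    )

    status = np.full(NA, _GROWING, dtype=int)
    connect_time = np.full(NA, np.nan)
    slow = np.zeros(NA, dtype=int)
    nosig = np.zeros(NA, dtype=int)
    z_start = pos[:, 2].copy()
    last_src_pos = pos.copy()
    vz_full = np.zeros(NA)

    rec_t = [0.0]
    rec_pos = [pos.copy()]
    rec_vz = [vz_full.copy()]
    rec_status = [status.copy()]

    t = 0.0
    step = 0
    dt_g = cfg.dt_growth
    while step < n_steps_max:
        growing = np.nonzero(status == _GROWING)[0]
        if growing.size == 0:
            break
        if cones_release and step > 0 and step % cfg.couple_every == 0:
            moved = float(np.max(np.linalg.norm(pos - last_src_pos, axis=1)))
            if moved >= cfg.refresh_min_move * lattice.dx:
                sources.cones = body_center(pos)
                for _ in range(relax):
                    lbm_step(state, sources, params, factors=(INHIBITOR, PROMOTER))
                last_src_pos = pos.copy()

        dxv = pos[growing, 0] - x0
        dyv = pos[growing, 1] - y0
        r = np.hypot(dxv, dyv)
        pole = r < POLE_EPS * geom.ra

        if cfg.force_projection == "tangent":
            m = growing.size
            V = np.zeros((m, 3))
            vz = np.zeros(m)
            ok = np.ones(m, dtype=bool)
            on_surface = ~pole
            if on_surface.any():
                # sense along the substrate: symmetric sample points on the
                # surface meridian, directional derivative across ~2Δx; the
                # sampling points are lifted half a cell off the wall (the
                # cone's body extends outward from the substrate) so that the
                # solid-masked interpolation treats all three points alike
                h = lattice.dx
                sel = growing[on_surface]
                tang = meridian_tangent(pos[sel], geom)
                lift = 0.5 * lattice.dx * surface_normal(pos[sel], geom)
                plus = project_to_surface(pos[sel] + h * tang, geom) + lift
                minus = project_to_surface(pos[sel] - h * tang, geom) + lift
                stack = np.concatenate([pos[sel] + lift, plus, minus], axis=0)
                vals = sample_fields(state, stack)  # (3 factors, 3k)
                k = sel.size
                c0, cp, cm = vals[:, :k], vals[:, k : 2 * k], vals[:, 2 * k :]
                rhoS = c0.sum(axis=0)
                ok_s = rhoS > 0.0
                safe = np.where(ok_s, rhoS, 1.0)
                dists = np.linalg.norm(plus - minus, axis=1)
                dds = (cp - cm) / np.maximum(dists, 1e-12)[None, :]
                speed = (mob @ dds) * params.delta_r / safe
                speed[~ok_s] = 0.0
                V[on_surface] = speed[:, None] * tang
                ok[on_surface] = ok_s
            if pole.any():
                # past the top pole the constraint is released
                grads, concs = sample_gradients_and_concentrations(
                    state, pos[growing[pole]]
                )
                rhoS = concs.sum(axis=1)
                ok_p = rhoS > 0.0
                safe = np.where(ok_p, rhoS, 1.0)
                p = grads * (params.delta_r / safe[:, None, None])
                vfree = np.einsum("i,mij->mj", mob, p)
                vfree[~ok_p] = 0.0
                V[pole] = vfree
                ok[pole] = ok_p
            vz = V[:, 2]
        else:
            grads, concs = sample_gradients_and_concentrations(state, pos[growing])
            rhoS = concs.sum(axis=1)
            ok = rhoS > 0.0
            safe = np.where(ok, rhoS, 1.0)
            p = grads * (params.delta_r / safe[:, None, None])  # (m, factors, axes)
            vel_free = np.einsum("i,mij->mj", mob, p)
            vel_free[~ok] = 0.0
            vz = vel_free[:, 2]
            r_safe = np.where(pole, 1.0, r)
            Vr = geom.ra**2 * (z0 - pos[growing, 2]) * vz / (geom.rz**2 * r_safe)
            V = np.column_stack([Vr * dxv / r_safe, Vr * dyv / r_safe, vz])
            V[pole] = vel_free[pole]  # constraint released past the pole

        # velocity batching: the sampled velocity is reused for as many unit
        # steps as keep the fastest cone's displacement below ~0.1 cells (and
        # never across a field-coupling boundary), so slowly crawling
        # populations do not resample an unchanged field every step
        max_disp = float(np.max(np.linalg.norm(V, axis=1))) * dt_g
        to_couple = cfg.couple_every - (step % cfg.couple_every)
        n_sub = to_couple if max_disp <= 0 else int(0.1 * lattice.dx / max_disp) + 1
        n_sub = max(1, min(n_sub, to_couple, n_steps_max - step))

        pos[growing] += V * (n_sub * dt_g)
        on_surf = growing[~pole]
        if on_surf.size:
            pos[on_surf] = project_to_surface(pos[on_surf], geom)
        t += n_sub * dt_g
        step += n_sub

        vz_full[:] = 0.0
        vz_full[growing] = vz
        nosig[growing] = np.where(ok, 0, nosig[growing] + n_sub)
        slow[growing] = np.where(vz <= cfg.vz_min, slow[growing] + n_sub, 0)

        d = np.linalg.norm(
            pos[growing][:, None, :] - placement.target_points[None, :, :], axis=2
        )
        hit = d.min(axis=1) < thr
        newly_connected = growing[hit]
        status[newly_connected] = _CONNECTED
        connect_time[newly_connected] = t
        stalled_mask = (~hit) & (
            (slow[growing] >= cfg.stall_window) | (nosig[growing] >= cfg.stall_window)
        )
        status[growing[stalled_mask]] = _STALLED

        # with batching each iteration covers >= history_every/n records
        rec_t.append(t)
        rec_pos.append(pos.copy())
        rec_vz.append(vz_full.copy())
        rec_status.append(status.copy())

    t_end = max(t, dt_g)
    traj_t = np.asarray(rec_t)
    traj_pos = np.asarray(rec_pos)
    traj_vz = np.asarray(rec_vz)
    traj_status = np.asarray(rec_status)

    cones = []
    for kk in range(NA):
        cone = GrowthCone(index=kk, pos=pos[kk], status=Status(_STATUS_NAMES[status[kk]]))
        cone.z_start = z_start[kk]
        cone.connect_time = None if np.isnan(connect_time[kk]) else float(connect_time[kk])
        cone.path = [
            (traj_t[m], *traj_pos[m, kk], traj_vz[m, kk]) for m in range(len(traj_t))
        ]
        cones.append(cone)

    vz_avg = average_drawing_speed(cones, t_end)
    conn_idx = np.nonzero(status == _CONNECTED)[0]
    if conn_idx.size:
        times = connect_time[conn_idx]
        order = np.lexsort((conn_idx, times))
        representative = int(conn_idx[order[(conn_idx.size - 1) // 2]])
    else:
        representative = int(np.argmax(pos[:, 2] - z_start))

    provenance = {
        "config": cfg.to_dict(),
        "resolved_params": params.to_dict(),
        "code_version": __version__,
        "lattice": {"n": lattice.n, "dx": lattice.dx, "n_fluid": lattice.n_fluid},
        "field_dt": state.dt,
        "tau": [float(x) for x in state.tau],
        "relax_steps": relax,
        "burnin": burn_info,
        "growth_steps": step,
        "t_max": t_max,
    }
    result = ScenarioResult(
        config=cfg,
        n_connected=int((status == _CONNECTED).sum()),
        n_stalled=int((status == _STALLED).sum()),
        vz_avg=vz_avg,
        connect_times=connect_time,
        statuses=[_STATUS_NAMES[s] for s in status],
        t_end=t_end,
        cones=cones,
        representative=representative,
        traj_t=traj_t,
        traj_pos=traj_pos,
        traj_vz=traj_vz,
        traj_status=traj_status,
        provenance=provenance,
        flags={"burnin_converged": burn_info["converged"]},
        fields=state._rho.copy() if cfg.keep_fields else None,
        lattice=lattice,
    )
    if cache:
        _SCENARIO_CACHE[key] = result
    return result


# ----------------------------------------------------------------------
# sweeps


def run_eta2_sweep(
    eta2_values: Sequence[float] = (0.03, 0.04, 0.05, 0.06, 0.07),
    preset: str = "desk",
    cache: bool = True,
    **preset_kw,
) -> SweepResult:
    """Inhibitor-ratio study: one run per η2, all else fixed at the baseline.

    Values may be given as fractions (0.03) or percent (3); rows are ordered
    by increasing η2.
    """
    if len(eta2_values) == 0:
        raise ValueError("eta2_values must be non-empty")
    vals = sorted(float(v) / 100.0 if float(v) > 1.0 else float(v) for v in eta2_values)
    make = desk_preset if preset == "desk" else full_preset
    rows = [run_scenario(make(eta2=v, **preset_kw), cache=cache) for v in vals]
    return SweepResult(rows=rows)


def run_scar_sweep(
    cases: Sequence[int | tuple[float, float]] = (1, 2, 3, 4, 5),
    preset: str = "desk",
    cache: bool = True,
    **preset_kw,
) -> SweepResult:
    """Scar size/shape study at η2 = η3 = 3%.

    ``cases`` are case numbers from :data:`SCAR_CASES` or explicit
    (ra/L, rz/L) pairs.
    """
    make = desk_preset if preset == "desk" else full_preset
    rows = []
    for case in cases:
        if isinstance(case, int):
            if case not in SCAR_CASES:
                raise ValueError(f"unknown scar case #{case}")
            ra_frac, rz_frac = SCAR_CASES[case]
            label = None
        else:
            ra_frac, rz_frac = case
            label = None
        cfg = make(eta2=0.03, eta3=0.03, ra_frac=ra_frac, rz_frac=rz_frac, **preset_kw)
        rows.append(run_scenario(cfg, cache=cache))
    return SweepResult(rows=rows)
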