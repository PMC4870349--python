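"""Result and field export: CSV tables, trajectory files, sections, VTK, run logs.

All outputs are plain text.  VTK snapshots use the legacy ASCII
STRUCTURED_POINTS format (one scalar array per factor), readable by ParaView
and friends; exports are idempotent (re-export overwrites with identical
bytes for identical results).
"""

from __future__ import annotations

import json
import os
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "write_vtk_structured_points",
    "write_field_csv",
    "write_midplane_section",
    "export_results",
]

_FACTOR_NAMES = ("rho1_attractant", "rho2_inhibitor", "rho3_promoter")


def write_vtk_structured_points(
    path: str, arrays: Mapping[str, np.ndarray], dx: float, origin: float = 0.0
) -> None:
    """Write scalar lattices to a legacy-ASCII VTK STRUCTURED_POINTS file."""
    arrays = dict(arrays)
    first = next(iter(arrays.values()))
    n = first.shape
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("gliaxon field snapshot\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {n[0]} {n[1]} {n[2]}\n")
        fh.write(f"ORIGIN {origin:.9g} {origin:.9g} {origin:.9g}\n")
        fh.write(f"SPACING {dx:.9g} {dx:.9g} {dx:.9g}\n")
        fh.write(f"POINT_DATA {n[0] * n[1] * n[2]}\n")
        for name, arr in arrays.items():
            if arr.shape != n:
                raise ValueError(f"array {name!r} has shape {arr.shape}, expected {n}")
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            # VTK expects x fastest; arrays are indexed [x, y, z]
            flat = np.transpose(arr, (2, 1, 0)).ravel()
            np.savetxt(fh, flat.reshape(-1, 1), fmt="%.9e")


def write_field_csv(path: str, rho: np.ndarray, dx: float) -> None:
    """Flat (x, y, z, ρ1, ρ2, ρ3) CSV of a (3, n, n, n) concentration stack."""
    n = rho.shape[1]
    ax = (np.arange(n) + 0.5) * dx
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    df = pd.DataFrame(
        {
            "x": X.ravel(),
            "y": Y.ravel(),
            "z": Z.ravel(),
            "rho1": rho[0].ravel(),
            "rho2": rho[1].ravel(),
            "rho3": rho[2].ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.9e")


def write_midplane_section(path: str, rho_i: np.ndarray) -> None:
    """Longitudinal mid-plane section (y = L/2) of one factor as a CSV matrix.

    Rows are x nodes, columns z nodes — the rendering layout of the
    concentration-section figures.
    """
    n = rho_i.shape[0]
    section = rho_i[:, n // 2, :]
    np.savetxt(path, section, delimiter=",", fmt="%.9e")


def _trajectories_frame(result) -> pd.DataFrame:
    status_names = {0: "growing", 1: "stalled", 2: "connected"}
    recs = []
    nrec, na = result.traj_vz.shape
    for k in range(na):
        for m in range(nrec):
            recs.append(
                (
                    k,
                    result.traj_t[m],
                    result.traj_pos[m, k, 0],
                    result.traj_pos[m, k, 1],
                    result.traj_pos[m, k, 2],
                    result.traj_vz[m, k],
                    status_names[int(result.traj_status[m, k])],
                )
            )
    return pd.DataFrame.from_records(
        recs, columns=["axon_id", "t", "x", "y", "z", "Vz", "status"]
    )


def export_results(result, outdir: str) -> list[str]:
    """Export a ScenarioResult or SweepResult to ``outdir``; returns paths.

    Writes the summary CSV (one row per scenario: label, vz_ave, n_connected,
    ...), per-axon trajectory CSVs, a JSON run log with full provenance, and —
    when the scenario kept its final fields — mid-plane sections and a VTK
    snapshot.
    """
    os.makedirs(outdir, exist_ok=True)
    rows = result.rows if hasattr(result, "rows") else [result]
    written: list[str] = []

    from .experiments import SweepResult  # local import to avoid a cycle

    summary = SweepResult(rows=rows).to_dataframe()
    p = os.path.join(outdir, "summary.csv")
    summary.to_csv(p, index=False, float_format="%.9e")
    written.append(p)

    for r in rows:
        stem = r.label.replace("/", "_")
        p = os.path.join(outdir, f"trajectories_{stem}.csv")
        _trajectories_frame(r).to_csv(p, index=False, float_format="%.9e")
        written.append(p)

        p = os.path.join(outdir, f"runlog_{stem}.json")
        with open(p, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(r.provenance, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(p)

        if r.fields is not None and r.lattice is not None:
            p = os.path.join(outdir, f"section_rho1_{stem}.csv")
            write_midplane_section(p, r.fields[0])
            written.append(p)
            p = os.path.join(outdir, f"fields_{stem}.vtk")
            write_vtk_structured_points(
                p,
                dict(zip(_FACTOR_NAMES, r.fields)),
                dx=r.lattice.dx,
                origin=r.lattice.dx / 2,
            )
            written.append(p)
    return written
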