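"""Text-format outputs: legacy-ASCII VTK structured points, convergence
CSV, and JSON run manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["write_vtk_structured_points", "write_convergence_csv", "write_manifest"]


def write_vtk_structured_points(path, fields: dict, spacing: float = 1.0) -> None:
    """Write scalar/vector fields on a regular grid as legacy ASCII VTK.

    ``fields`` maps names to arrays: scalars of shape (nx, ny[, nz]) or
    vectors with a trailing component axis.  Point data is emitted in VTK
    x-fastest order; 2D grids are written with nz = 1.
    """
    if not fields:
        raise ValueError("no fields to write")
    grid = min((v.shape for v in fields.values()), key=len)  # scalars are shortest
    nx, ny = grid[0], grid[1]
    nz = grid[2] if len(grid) == 3 else 1
    lines = [
        "# vtk DataFile Version 3.0",
        "crumbflow fields",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        "ORIGIN 0 0 0",
        f"SPACING {spacing:g} {spacing:g} {spacing:g}",
        f"POINT_DATA {nx * ny * nz}",
    ]

    def flat(a):
        # VTK expects x varying fastest: transpose to (z, y, x) then ravel
        if a.ndim == 2:
            a = a[:, :, None]
        return a.transpose(2, 1, 0).ravel()

    for name, arr in fields.items():
        arr = np.asarray(arr, dtype=np.float64)
        is_vector = arr.ndim == len(grid) + 1
        if is_vector:
            comps = [flat(arr[..., i]) for i in range(arr.shape[-1])]
            while len(comps) < 3:
                comps.append(np.zeros_like(comps[0]))
            lines.append(f"VECTORS {name} double")
            lines.extend(
                f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in zip(*comps)
            )
        else:
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.9g}" for v in flat(arr))
    Path(path).write_text("\n".join(lines) + "\n")


def write_convergence_csv(path, history, nu: float | None = None,
                          force: float | None = None) -> None:
    """History CSV: iteration, per-iteration residual, Ud, running k."""
    lines = ["iteration,residual,Ud,k_lattice"]
    for it, res, ud in history:
        k = ud * nu / force if (nu is not None and force) else float("nan")
        lines.append(f"{it},{res:.9g},{ud:.9g},{k:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(path, entries: dict) -> None:
    """JSON manifest of a run (inputs, seeds, parameters, versions)."""
    import crumbflow

    payload = {"crumbflow_version": getattr(crumbflow, "__version__", "0")}
    payload.update(_jsonable(entries))
    Path(path).write_text(json.dumps(payload, indent=1, default=str))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
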