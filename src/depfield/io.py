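"""Serialization of sampled field grids: long-format CSV and legacy VTK."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .series import FieldGrid

__all__ = ["grid_to_frame", "export_grid", "read_grid_csv"]


def grid_to_frame(grid: FieldGrid) -> pd.DataFrame:
    """Flatten a FieldGrid to a long-format table (one row per lattice node)."""
    X, Y = np.meshgrid(grid.x_star, grid.y_star)
    V, H = grid.drive.V_rms, grid.geometry.H
    return pd.DataFrame({
        "x_star": X.ravel(),
        "y_star": Y.ravel(),
        "phi": grid.phi.ravel(),
        "phi_norm": (grid.phi / V).ravel(),
        "Ex": grid.Ex.ravel(),
        "Ey": grid.Ey.ravel(),
        "E_norm": (np.hypot(grid.Ex, grid.Ey) * H / V).ravel(),
        "gradE2_x": grid.grad_E2_x.ravel(),
        "gradE2_y": grid.grad_E2_y.ravel(),
        "Fdep_norm": grid.F_norm.ravel(),
    })


def export_grid(grid: FieldGrid, fmt: str, path) -> Path:
    """Write a FieldGrid to ``path`` as ``csv`` or legacy ASCII ``vtk``.

    CSV uses full-precision ``repr`` serialization, so a re-read reproduces
    every value bit-exactly.  VTK writes a STRUCTURED_POINTS dataset with
    the potential as a scalar field and E / grad|E|^2 as vector fields
    (z-component zero), readable by ParaView and friends.
    """
    path = Path(path)
    if grid.phi.size == 0:
        raise ValueError("cannot export an empty grid")
    try:
        if fmt == "csv":
            # %.17g round-trips every IEEE double bit-exactly
            grid_to_frame(grid).to_csv(path, index=False, float_format="%.17g")
        elif fmt == "vtk":
            _write_vtk(grid, path)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except OSError as exc:
        raise OSError(f"failed writing grid to {path}: {exc}") from exc
    return path


def read_grid_csv(path) -> pd.DataFrame:
    """Re-read an exported CSV (bit-exact round trip of the written values)."""
    return pd.read_csv(path, float_precision="round_trip")


def _write_vtk(grid: FieldGrid, path: Path) -> None:
    ny, nx = grid.phi.shape
    geom = grid.geometry
    lines = [
        "# vtk DataFile Version 3.0",
        "depfield sampled channel cross-section",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} 1",
        "ORIGIN 0 0 0",
        f"SPACING {geom.L / (nx - 1):.9e} {geom.H / (ny - 1):.9e} 1",
        f"POINT_DATA {nx * ny}",
        "SCALARS phi double 1",
        "LOOKUP_TABLE default",
    ]
    lines.extend(f"{v:.9e}" for v in grid.phi.ravel())
    lines.append("VECTORS E double")
    lines.extend(f"{ex:.9e} {ey:.9e} 0.0"
                 for ex, ey in zip(grid.Ex.ravel(), grid.Ey.ravel()))
    lines.append("VECTORS gradE2 double")
    lines.extend(f"{gx:.9e} {gy:.9e} 0.0"
                 for gx, gy in zip(np.nan_to_num(grid.grad_E2_x).ravel(),
                                   np.nan_to_num(grid.grad_E2_y).ravel()))
    path.write_text("\n".join(lines) + "\n")
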