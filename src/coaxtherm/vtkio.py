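"""Minimal legacy-ASCII VTK writers for the axisymmetric grids and images.

Writes VTK 2.0 structured-grid / structured-points files by hand (plain
text), enough for field inspection in ParaView-class viewers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import MaterialMap

__all__ = ["write_structured_grid", "write_image"]


def write_structured_grid(
    path,
    mmap: MaterialMap,
    cell_fields: dict[str, np.ndarray],
    title: str = "coaxtherm field",
) -> Path:
    """Write cell-centered (r, z) fields as a 2D structured grid (x=r, y=z)."""
    path = Path(path)
    nr, nz = mmap.shape
    rc, zc = mmap.r_centers, mmap.z_centers
    lines = [
        "# vtk DataFile Version 2.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_GRID",
        f"DIMENSIONS {nr} {nz} 1",
        f"POINTS {nr * nz} float",
    ]
    R, Z = np.meshgrid(rc, zc, indexing="ij")
    pts = np.column_stack([R.ravel(order="F"), Z.ravel(order="F"), np.zeros(nr * nz)])
    lines += [" ".join(f"{v:.6e}" for v in p) for p in pts]
    lines.append(f"POINT_DATA {nr * nz}")
    for name, field in cell_fields.items():
        if field.shape != (nr, nz):
            raise ValueError(f"field {name!r} has shape {field.shape}, expected {(nr, nz)}")
        lines.append(f"SCALARS {name.replace(' ', '_')} float 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.6e}" for v in np.asarray(field, float).ravel(order="F")]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_image(path, x_cm, z_cm, values, name="temperature_C", title="coaxtherm image") -> Path:
    """Write a uniform 2D image (e.g. an IR snapshot) as structured points."""
    path = Path(path)
    values = np.asarray(values, float)
    nx, nz = values.shape
    dx = x_cm[1] - x_cm[0] if nx > 1 else 1.0
    dz = z_cm[1] - z_cm[0] if nz > 1 else 1.0
    lines = [
        "# vtk DataFile Version 2.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {nz} 1",
        f"ORIGIN {x_cm[0]:.6e} {z_cm[0]:.6e} 0.0",
        f"SPACING {dx:.6e} {dz:.6e} 1.0",
        f"POINT_DATA {nx * nz}",
        f"SCALARS {name} float 1",
        "LOOKUP_TABLE default",
    ]
    lines += [f"{v:.6e}" for v in values.ravel(order="F")]
    path.write_text("\n".join(lines) + "\n")
    return path
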