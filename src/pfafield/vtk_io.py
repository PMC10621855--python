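"""Minimal legacy-ASCII VTK writers for meshes, fields and isolines.

Writes VTK DataFile 2.0 text files readable by ParaView/VisIt: a
rectilinear grid with cell labels for rasterized tissue maps, an
unstructured triangle grid with nodal/cell fields for solutions, and
polydata polylines for lesion isolines.  Only the small legacy subset
needed here is implemented.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import LabelGrid
from .lesion import VCM_PER_VM
from .solver import FieldSolution

__all__ = ["write_label_grid_vtk", "write_solution_vtk", "write_isolines_vtk"]


def _fmt(arr: np.ndarray, per_line: int = 6) -> str:
    flat = np.asarray(arr).ravel()
    lines = []
    for i in range(0, len(flat), per_line):
        lines.append(" ".join(f"{v:.7g}" for v in flat[i:i + per_line]))
    return "\n".join(lines)


def write_label_grid_vtk(grid: LabelGrid, path: str | Path) -> None:
    """Rasterized tissue map as a RECTILINEAR_GRID with a cell label array."""
    nr, nz = len(grid.r_edges), len(grid.z_edges)
    # VTK x <- r, y <- z, z <- 1 plane
    labels = np.asarray(grid.labels)
    body = [
        "# vtk DataFile Version 2.0",
        "pfafield tissue label raster (r=x mm, depth z=y mm)",
        "ASCII",
        "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {nr} {nz} 1",
        f"X_COORDINATES {nr} float", _fmt(grid.r_edges),
        f"Y_COORDINATES {nz} float", _fmt(grid.z_edges),
        "Z_COORDINATES 1 float", "0",
        f"CELL_DATA {(nr - 1) * (nz - 1)}",
        "SCALARS tissue_label int 1",
        "LOOKUP_TABLE default",
        "\n".join(" ".join(str(int(v)) for v in labels[:, j])
                  for j in range(labels.shape[1])),
    ]
    Path(path).write_text("\n".join(body) + "\n")


def write_solution_vtk(sol: FieldSolution, path: str | Path) -> None:
    """Field solution as an UNSTRUCTURED_GRID of triangles.

    Point data: phi (V); cell data: E magnitude (V/cm), |J| (A/cm^2),
    sigma (S/m) and tissue label.  Coordinates in mm.
    """
    mesh = sol.mesh
    nodes = mesh.nodes / 1e-3
    tri = mesh.elements[mesh.active]
    ne = tri.shape[0]
    cells = "\n".join(f"3 {a} {b} {c}" for a, b, c in tri)
    body = [
        "# vtk DataFile Version 2.0",
        f"pfafield solution V={sol.V_applied:.1f} I={sol.I_delivered:.3f}",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} float",
        _fmt(np.column_stack([nodes, np.zeros(len(nodes))])),
        f"CELLS {ne} {4 * ne}", cells,
        f"CELL_TYPES {ne}", "\n".join(["5"] * ne),
        f"POINT_DATA {mesh.n_nodes}",
        "SCALARS phi_V float 1", "LOOKUP_TABLE default", _fmt(sol.phi),
        f"CELL_DATA {ne}",
        "SCALARS E_V_per_cm float 1", "LOOKUP_TABLE default",
        _fmt(sol.E_mag[mesh.active] * VCM_PER_VM),
        "SCALARS J_A_per_cm2 float 1", "LOOKUP_TABLE default",
        _fmt(sol.J_mag[mesh.active] * 1e-4),
        "SCALARS sigma_S_per_m float 1", "LOOKUP_TABLE default",
        _fmt(sol.sigma[mesh.active]),
        "SCALARS tissue_label int 1", "LOOKUP_TABLE default",
        "\n".join(str(int(v)) for v in mesh.elem_label[mesh.active]),
    ]
    Path(path).write_text("\n".join(body) + "\n")


def write_isolines_vtk(isolines: list[np.ndarray], path: str | Path) -> None:
    """Lesion isoline polylines ((r, z) mm) as VTK POLYDATA."""
    pts = np.vstack(isolines) if isolines else np.empty((0, 2))
    offsets = np.cumsum([0] + [len(p) for p in isolines])
    lines = []
    for k, poly in enumerate(isolines):
        ids = range(offsets[k], offsets[k + 1])
        lines.append(f"{len(poly)} " + " ".join(str(i) for i in ids))
    body = [
        "# vtk DataFile Version 2.0",
        "pfafield lethal-field isolines (mm)",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(pts)} float",
        _fmt(np.column_stack([pts, np.zeros(len(pts))])),
        f"LINES {len(isolines)} {sum(len(p) + 1 for p in isolines)}",
        "\n".join(lines),
    ]
    Path(path).write_text("\n".join(body) + "\n")
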