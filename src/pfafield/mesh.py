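"""Graded structured triangulation of the axisymmetric domain.

The mesh is a tensor product of graded 1D point sets in r and z, each
cell split into two triangles.  Grid lines are snapped onto every
horizontal/vertical material interface reported by the tissue map, so
elements never straddle the stratified interfaces, and the electrode
surface is resolved at the fine target size.  Element labels are
assigned from the tissue map at element centroids; electrode and shaft
elements are excluded from the conductive domain and their surface
nodes become Dirichlet/natural boundaries respectively.

Coordinates are stored in metres (SI); the tissue map speaks mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import TissueLabel, TissueMap

__all__ = ["Mesh", "generate_mesh", "tensor_mesh"]

MM = 1e-3


def _fill_segment(a: float, b: float, ha: float, hb: float,
                  growth: float = 0.18) -> np.ndarray:
    """Graded points on [a, b] with target sizes ha, hb at the ends.

    The local size grows roughly linearly (rate ``growth``) with the
    distance from the nearer endpoint, capped at the larger endpoint
    size, which approximates geometric grading with ratio 1 + growth.
    Endpoints are included; the interior points are rescaled so the last
    step lands exactly on ``b``.
    """
    L = b - a
    hmin = min(ha, hb)
    hmax = max(ha, hb)
    if L <= 1.5 * hmin:
        return np.array([a, b])
    pts = [0.0]
    x = 0.0
    while True:
        h = min(ha + growth * x, hb + growth * (L - x), hmax)
        x += h
        if x >= L - 0.3 * h:
            break
        pts.append(x)
    arr = np.asarray(pts + [L])
    return a + arr * (L / arr[-1])


def _graded_axis(breaks: list[tuple[float, float]]) -> np.ndarray:
    """Concatenate graded segments between (position, local size) breakpoints."""
    breaks = sorted(breaks)
    out = [np.array([breaks[0][0]])]
    for (a, ha), (b, hb) in zip(breaks[:-1], breaks[1:]):
        if b - a < 1e-9:
            continue
        out.append(_fill_segment(a, b, ha, hb)[1:])
    return np.concatenate(out)


def _insert_snapped(pts: np.ndarray, keys: list[float]) -> np.ndarray:
    """Snap the nearest existing point onto each key coordinate."""
    pts = pts.copy()
    for k in keys:
        i = int(np.argmin(np.abs(pts - k)))
        if 0 < i < len(pts) - 1:
            pts[i] = k
        elif abs(pts[i] - k) > 1e-9:
            pts = np.sort(np.append(pts, k))
    return np.unique(pts)


@dataclass
class Mesh:
    """Conforming triangulation of the conductive half-plane (SI units).

    Nodes lie on a tensor grid ``r_lines`` x ``z_lines`` (metres);
    ``elements`` are triangles over all grid cells, with ``active``
    marking those inside the conductive domain (not electrode/shaft).
    """

    nodes: np.ndarray            # (n_nodes, 2) [r, z] in m
    elements: np.ndarray         # (n_elem, 3) int
    elem_label: np.ndarray       # (n_elem,) TissueLabel ints
    active: np.ndarray           # (n_elem,) bool
    electrode_nodes: np.ndarray  # node indices, Dirichlet V
    ground_nodes: np.ndarray     # node indices, Dirichlet 0
    r_lines: np.ndarray          # (nr,) m
    z_lines: np.ndarray          # (nz,) m
    tissue_map: TissueMap | None = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.r_lines), len(self.z_lines)

    def node_grid(self, values: np.ndarray) -> np.ndarray:
        """Reshape a nodal vector onto the (nr, nz) tensor grid."""
        nr, nz = self.shape
        return np.asarray(values).reshape(nr, nz)

    def centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def min_angle_deg(self) -> float:
        """Smallest interior angle over active elements (mesh quality)."""
        tri = self.nodes[self.elements[self.active]]
        angles = []
        for k in range(3):
            a = tri[:, (k + 1) % 3] - tri[:, k]
            b = tri[:, (k + 2) % 3] - tri[:, k]
            cosang = np.einsum("ij,ij->i", a, b) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        return float(np.min(angles))


def tensor_mesh(r_lines_mm: np.ndarray, z_lines_mm: np.ndarray,
                label_fn, electrode_fn, ground_fn,
                tissue_map: TissueMap | None = None) -> Mesh:
    """Build a Mesh on an explicit tensor grid (mm) with callable geometry.

    ``label_fn(r, z)`` maps point arrays (mm) to TissueLabel ints (used at
    element centroids); ``electrode_fn``/``ground_fn`` are nodal predicates
    (mm) selecting the Dirichlet sets.  Intended for idealized
    configurations (hemispherical electrodes, spherical inclusions)
    whose analytic solutions serve as solver cross-checks.
    """
    r_pts = np.unique(np.asarray(r_lines_mm, dtype=float))
    z_pts = np.unique(np.asarray(z_lines_mm, dtype=float))
    nr, nz = len(r_pts), len(z_pts)
    R, Z = np.meshgrid(r_pts, z_pts, indexing="ij")
    nodes_mm = np.column_stack([R.ravel(), Z.ravel()])

    i_idx, j_idx = np.meshgrid(np.arange(nr - 1), np.arange(nz - 1),
                               indexing="ij")
    n00 = (i_idx * nz + j_idx).ravel()
    n10, n01 = n00 + nz, n00 + 1
    n11 = n10 + 1
    parity = ((i_idx + j_idx) % 2 == 0).ravel()
    tri_a = np.where(parity[:, None], np.column_stack([n00, n10, n11]),
                     np.column_stack([n00, n10, n01]))
    tri_b = np.where(parity[:, None], np.column_stack([n00, n11, n01]),
                     np.column_stack([n10, n11, n01]))
    elements = np.vstack([tri_a, tri_b]).astype(np.int64)

    cent = nodes_mm[elements].mean(axis=1)
    elem_label = np.asarray(label_fn(cent[:, 0], cent[:, 1]), dtype=np.int32)
    inactive = (int(TissueLabel.ELECTRODE), int(TissueLabel.INSULATED_SHAFT))
    active = ~np.isin(elem_label, inactive)

    touch_active = np.zeros(nodes_mm.shape[0], dtype=bool)
    touch_active[np.unique(elements[active])] = True
    elec = np.asarray(electrode_fn(nodes_mm[:, 0], nodes_mm[:, 1]), dtype=bool)
    gnd = np.asarray(ground_fn(nodes_mm[:, 0], nodes_mm[:, 1]), dtype=bool)
    return Mesh(nodes=nodes_mm * MM, elements=elements, elem_label=elem_label,
                active=active,
                electrode_nodes=np.flatnonzero(elec & touch_active),
                ground_nodes=np.flatnonzero(gnd & ~elec & touch_active),
                r_lines=r_pts * MM, z_lines=z_pts * MM, tissue_map=tissue_map)


def generate_mesh(tissue_map: TissueMap, h_fine: float = 0.05,
                  h_coarse: float = 3.0) -> Mesh:
    """Mesh a tissue map with near-electrode size ``h_fine`` mm, far-field
    ``h_coarse`` mm.

    The fine zone covers the electrode and the expected lesion extent
    (a few mm around the tip); sizes grade geometrically outward.
    """
    if not 0 < h_fine < h_coarse:
        raise ValueError("need 0 < h_fine < h_coarse")
    s = tissue_map.spec
    hf, hc = h_fine, h_coarse
    re_ = s.electrode_radius

    r_breaks = [(0.0, hf), (re_, hf), (re_ + 1.5, 1.6 * hf),
                (7.0, 4.0 * hf), (14.0, min(14.0 * hf, hc)),
                (s.domain_radius, hc)]
    z_breaks = [(s.z_top, hc), (s.electrode_top_z - 1.0, 8.0 * hf),
                (s.electrode_top_z, hf), (s.tip_z, hf),
                (s.tip_z + 1.0, 1.4 * hf), (3.0, 2.0 * hf),
                (5.0, 2.5 * hf), (s.wall_thickness, 4.0 * hf),
                (s.wall_thickness + s.epicardial_fat_thickness, 5.0 * hf),
                (s.wall_thickness + s.epicardial_fat_thickness + 3.0,
                 min(16.0 * hf, hc)),
                (s.z_bottom, hc)]

    r_pts = _graded_axis([(p, h) for p, h in r_breaks])
    z_pts = _graded_axis([(p, h) for p, h in z_breaks])
    r_pts = _insert_snapped(r_pts, tissue_map.interface_r_lines())
    z_pts = _insert_snapped(z_pts, tissue_map.interface_z_lines() + [0.0])

    nr, nz = len(r_pts), len(z_pts)
    R, Z = np.meshgrid(r_pts, z_pts, indexing="ij")
    nodes_mm = np.column_stack([R.ravel(), Z.ravel()])

    # node index (i, j) -> i * nz + j
    i_idx, j_idx = np.meshgrid(np.arange(nr - 1), np.arange(nz - 1),
                               indexing="ij")
    n00 = (i_idx * nz + j_idx).ravel()
    n10 = n00 + nz
    n01 = n00 + 1
    n11 = n10 + 1
    # alternate the cell diagonal to avoid directional bias
    parity = ((i_idx + j_idx) % 2 == 0).ravel()
    tri_a = np.where(parity[:, None], np.column_stack([n00, n10, n11]),
                     np.column_stack([n00, n10, n01]))
    tri_b = np.where(parity[:, None], np.column_stack([n00, n11, n01]),
                     np.column_stack([n10, n11, n01]))
    elements = np.vstack([tri_a, tri_b]).astype(np.int64)

    cent = nodes_mm[elements].mean(axis=1)
    elem_label = tissue_map.labels_at(cent[:, 0], cent[:, 1])
    if np.any(elem_label < 0):
        raise RuntimeError("unlabeled elements: tissue regions do not tile "
                           "the domain")
    inactive_labels = (int(TissueLabel.ELECTRODE), int(TissueLabel.INSULATED_SHAFT))
    active = ~np.isin(elem_label, inactive_labels)

    # Dirichlet electrode nodes: shared by an active and an electrode element
    n_nodes = nodes_mm.shape[0]
    touch_active = np.zeros(n_nodes, dtype=bool)
    touch_elec = np.zeros(n_nodes, dtype=bool)
    touch_active[np.unique(elements[active])] = True
    touch_elec[np.unique(elements[elem_label == int(TissueLabel.ELECTRODE)])] = True
    electrode_nodes = np.flatnonzero(touch_active & touch_elec)

    # ground: outer boundaries (top of blood, outer radius, bottom)
    on_outer = (np.isclose(nodes_mm[:, 0], r_pts[-1])
                | np.isclose(nodes_mm[:, 1], z_pts[0])
                | np.isclose(nodes_mm[:, 1], z_pts[-1]))
    ground_nodes = np.flatnonzero(on_outer & touch_active)

    return Mesh(nodes=nodes_mm * MM, elements=elements,
                elem_label=elem_label.astype(np.int32), active=active,
                electrode_nodes=electrode_nodes, ground_nodes=ground_nodes,
                r_lines=r_pts * MM, z_lines=z_pts * MM,
                tissue_map=tissue_map)
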