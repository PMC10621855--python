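"""Lesion-size metrics from the lethal-field isoline.

The irreversible-electroporation lesion is the superlevel set
|E| >= threshold (default 1000 V/cm) of the converged field inside the
tissue.  The field is resampled from the FEM solution onto a fine
structured grid of the tissue half-plane; the isoline is extracted by
marching squares.  Only the connected superlevel component reaching the
electrode counts as the ablation lesion proper: detached satellite
pockets (possible inside distant fat) are reported separately.

Metrics follow the conventional reporting: depth is the maximum extent
below the undisturbed endocardial surface (z = 0), measured over the
lesion component regardless of which tissue the isoline crosses;
surface width is twice the maximal lesion radius at the surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.interpolate import RegularGridInterpolator
from skimage import measure

from .geometry import TissueLabel, TissueMap
from .solver import FieldSolution

__all__ = ["LesionMetrics", "extract_isoline", "lesion_size",
           "axis_profile", "hotcold_points", "resample_field",
           "interface_flux_continuity"]

MM = 1e-3
VCM_PER_VM = 1e-2  # 1 V/m = 0.01 V/cm

_TISSUE_LABELS = (int(TissueLabel.MYOCARDIUM), int(TissueLabel.FIBROSIS),
                  int(TissueLabel.FAT), int(TissueLabel.CONNECTIVE))


@dataclass
class LesionMetrics:
    threshold: float            # V/cm
    depth: float                # mm, max z of the lesion component
    surface_width: float        # mm, 2 * max r at z = 0+
    isoline: list[np.ndarray]   # polylines, (n, 2) arrays of (r, z) mm
    volume: float = 0.0         # mm^3, revolved lesion component
    clamped_to_fat: bool = False
    fat_boundary_z: float | None = None
    n_satellites: int = 0


def _field_interpolator(sol: FieldSolution) -> RegularGridInterpolator:
    """Linear interpolant of the nodal-averaged |E| on the tensor grid (mm)."""
    mesh = sol.mesh
    E_node = sol.nodal_average(sol.E_mag)
    grid = mesh.node_grid(E_node)
    return RegularGridInterpolator(
        (mesh.r_lines / MM, mesh.z_lines / MM), grid,
        bounds_error=False, fill_value=0.0)


def resample_field(sol: FieldSolution, h: float = 0.025,
                   r_max: float | None = None, z_max: float | None = None
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Resample |E| (V/cm) on a fine cell-centered grid of the tissue half-plane.

    Returns ``(r_centers, z_centers, E_grid, tissue_mask)`` with the grid
    indexed ``[i_r, j_z]``; |E| is zero outside tissue so the marching
    squares isoline closes along the tissue boundary.
    """
    tmap = sol.mesh.tissue_map
    if tmap is None:
        raise ValueError("solution's mesh has no tissue map attached")
    s = tmap.spec
    r_max = r_max if r_max is not None else min(12.0, s.domain_radius)
    z_max = (z_max if z_max is not None
             else s.wall_thickness + s.epicardial_fat_thickness + 1.0)
    rc = np.arange(0.5 * h, r_max, h)
    zc = np.arange(0.5 * h, z_max, h)
    R, Z = np.meshgrid(rc, zc, indexing="ij")
    labels = tmap.labels_at(R.ravel(), Z.ravel()).reshape(R.shape)
    mask = np.isin(labels, _TISSUE_LABELS)
    pts = np.column_stack([R.ravel(), Z.ravel()])
    interp = _field_interpolator(sol)
    E = interp(pts).reshape(R.shape)
    # |E| is discontinuous across material interfaces (sigma jump in the
    # normal component); resample each tissue one-sided from its own
    # elements, falling back to the two-sided average where the one-sided
    # stencil is incomplete (non-conforming curved boundaries).
    mesh = sol.mesh
    grid_axes = (mesh.r_lines / MM, mesh.z_lines / MM)
    for lab_val in np.unique(labels[mask]):
        node_vals = sol.nodal_average(sol.E_mag,
                                      elem_mask=mesh.elem_label == lab_val)
        one_sided = RegularGridInterpolator(
            grid_axes, mesh.node_grid(node_vals),
            bounds_error=False, fill_value=np.nan)
        sel = (labels == lab_val).ravel()
        vals = one_sided(pts[sel])
        good = np.isfinite(vals)
        idx = np.flatnonzero(sel)[good]
        E.ravel()[idx] = vals[good]
    E = np.where(mask, E * VCM_PER_VM, 0.0)
    return rc, zc, E, mask


def _contours_mm(E: np.ndarray, thr: float, rc: np.ndarray, zc: np.ndarray
                 ) -> list[np.ndarray]:
    h_r = rc[1] - rc[0] if len(rc) > 1 else 1.0
    h_z = zc[1] - zc[0] if len(zc) > 1 else 1.0
    out = []
    for c in measure.find_contours(E, thr):
        r = rc[0] + c[:, 0] * h_r
        z = zc[0] + c[:, 1] * h_z
        out.append(np.column_stack([r, z]))
    return out


def extract_isoline(sol: FieldSolution, threshold: float = 1000.0,
                    h: float = 0.025) -> list[np.ndarray]:
    """Marching-squares polylines of |E| = threshold (V/cm) in the tissue.

    Returns a list of (n, 2) arrays of (r, z) in mm; empty if the
    threshold exceeds the global field maximum.
    """
    rc, zc, E, _ = resample_field(sol, h=h)
    return _contours_mm(E, threshold, rc, zc)


def _lesion_component(E: np.ndarray, thr: float, rc: np.ndarray,
                      zc: np.ndarray, tmap: TissueMap
                      ) -> tuple[np.ndarray, int]:
    """Connected superlevel component adjacent to the electrode tip.

    Returns (component mask, number of satellite components).
    """
    above = E >= thr
    lab, n_comp = measure.label(above, connectivity=1, return_num=True)
    if n_comp == 0:
        return np.zeros_like(above), 0
    tip_z = tmap.spec.tip_z
    i0 = int(np.argmin(np.abs(rc - 0.0)))
    j0 = int(np.argmin(np.abs(zc - (tip_z + (zc[1] - zc[0]))))) if len(zc) > 1 \
        else 0
    comp_id = lab[i0, j0]
    if comp_id == 0:
        # seed cell below threshold: pick the component closest to the tip
        R, Z = np.meshgrid(rc, zc, indexing="ij")
        d2 = R ** 2 + (Z - tip_z) ** 2
        d2 = np.where(lab > 0, d2, np.inf)
        comp_id = lab[np.unravel_index(int(np.argmin(d2)), d2.shape)]
    return lab == comp_id, n_comp - 1


def lesion_size(sol: FieldSolution, threshold: float = 1000.0,
                h: float = 0.025) -> LesionMetrics:
    """Depth, surface width and isoline of the lethal-field lesion."""
    tmap = sol.mesh.tissue_map
    rc, zc, E, _ = resample_field(sol, h=h)
    comp, n_sat = _lesion_component(E, threshold, rc, zc, tmap)
    if not comp.any():
        return LesionMetrics(threshold=threshold, depth=0.0,
                             surface_width=0.0, isoline=[],
                             n_satellites=n_sat)

    # isoline of the selected component only: zero the field elsewhere but
    # keep a one-cell halo so the sub-cell crossing positions are intact
    halo = comp.copy()
    halo[:-1] |= comp[1:]
    halo[1:] |= comp[:-1]
    halo[:, :-1] |= comp[:, 1:]
    halo[:, 1:] |= comp[:, :-1]
    E_sel = np.where(halo, E, 0.0)
    isolines = _contours_mm(E_sel, threshold, rc, zc)

    pts = np.vstack(isolines) if isolines else np.empty((0, 2))
    depth = float(pts[:, 1].max()) if len(pts) else float(zc[comp.any(axis=0)].max())

    # surface width: sub-cell crossing along the first tissue row (z = 0+)
    row = np.flatnonzero(comp[:, 0])
    if row.size:
        i_max = int(row.max())
        r_w = rc[i_max]
        if i_max + 1 < len(rc) and E[i_max + 1, 0] < threshold < E[i_max, 0]:
            frac = (E[i_max, 0] - threshold) / (E[i_max, 0] - E[i_max + 1, 0])
            r_w = rc[i_max] + frac * (rc[1] - rc[0])
        width = 2.0 * float(r_w)
    else:
        width = 0.0

    R, _Z = np.meshgrid(rc, zc, indexing="ij")
    volume = float((2.0 * np.pi * R[comp]).sum() * h * h)

    # fat clamping: is the deepest isoline point on a fat lower boundary?
    clamped = False
    fat_z = None
    if len(pts):
        deepest = pts[np.argmax(pts[:, 1])]
        lab_above = tmap.labels_at(np.array([deepest[0]]),
                                   np.array([max(deepest[1] - h, 0.0)]))[0]
        lab_below = tmap.labels_at(np.array([deepest[0]]),
                                   np.array([deepest[1] + h]))[0]
        if lab_above == int(TissueLabel.FAT) and lab_below != int(TissueLabel.FAT):
            clamped = True
            fat_z = float(deepest[1])
    return LesionMetrics(threshold=threshold, depth=depth,
                         surface_width=width, isoline=isolines,
                         volume=volume, clamped_to_fat=clamped,
                         fat_boundary_z=fat_z, n_satellites=n_sat)


def axis_profile(sol: FieldSolution, z_max: float = 15.0) -> pd.DataFrame:
    """Potential and field along the symmetry axis, z = 0 to ``z_max`` mm.

    Columns: ``z_mm``, ``phi_V``, ``E_Vcm``.  Nodes inside the electrode
    (z < insertion depth) carry the applied potential and no field.
    """
    mesh = sol.mesh
    z_mm = mesh.z_lines / MM
    sel = (z_mm >= 0.0) & (z_mm <= z_max)
    phi_grid = mesh.node_grid(sol.phi)
    E_grid = mesh.node_grid(sol.nodal_average(sol.E_mag))
    tip = mesh.tissue_map.spec.tip_z if mesh.tissue_map else 0.0
    phi_axis = phi_grid[0, sel].copy()
    inside = z_mm[sel] < tip
    phi_axis[inside] = sol.V_applied
    return pd.DataFrame({
        "z_mm": z_mm[sel],
        "phi_V": phi_axis,
        "E_Vcm": E_grid[0, sel] * VCM_PER_VM,
    })


def interface_flux_continuity(sol: FieldSolution, z_interface: float,
                              r_probe: float, r_halfwidth: float = 0.3,
                              band: float = 0.5) -> dict[str, float]:
    """Check the electromagnetic matching conditions at a horizontal interface.

    Across a conductivity jump the normal current density is continuous
    (sigma_1 * E_n,1 = sigma_2 * E_n,2) while the tangential field E_t
    is continuous.  Element fields are piecewise constant, so each side's
    flux is least-squares extrapolated to the interface from the element
    bands within ``band`` mm of it, at radius ``r_probe`` +/-
    ``r_halfwidth`` mm.

    Returns a dict with the extrapolated ``sigma_En`` and ``Et`` on each
    side (``_above`` = shallower) and their ratios.
    """
    mesh = sol.mesh
    cent = mesh.centroids() / MM
    out: dict[str, float] = {}
    for side, sgn in (("above", -1.0), ("below", 1.0)):
        sel = np.flatnonzero(
            mesh.active & (np.abs(cent[:, 0] - r_probe) < r_halfwidth)
            & (sgn * (cent[:, 1] - z_interface) > 0)
            & (sgn * (cent[:, 1] - z_interface) < band))
        if sel.size < 4:
            raise ValueError("too few elements next to the interface")
        zc_ = cent[sel, 1]
        flux = sol.sigma[sel] * np.abs(sol.E_vec[sel, 1])
        et = np.abs(sol.E_vec[sel, 0])
        zb = np.unique(np.round(zc_, 4))
        zb = zb[np.argsort(np.abs(zb - z_interface))][:4]
        zm, fm, tm = [], [], []
        for z0 in zb:
            m = np.isclose(zc_, z0, atol=1e-4)
            zm.append(z0)
            fm.append(flux[m].mean())
            tm.append(et[m].mean())
        deg = 1 if len(zm) > 1 else 0
        out[f"sigma_En_{side}"] = float(np.polyval(np.polyfit(zm, fm, deg),
                                                   z_interface))
        out[f"Et_{side}"] = float(np.polyval(np.polyfit(zm, tm, deg),
                                             z_interface))
    out["sigma_En_ratio"] = out["sigma_En_above"] / out["sigma_En_below"]
    out["Et_ratio"] = (out["Et_above"] / out["Et_below"]
                       if out["Et_below"] > 1e-12 else 1.0)
    return out


def hotcold_points(sol: FieldSolution, tmap: TissueMap | None = None,
                   offset: float = 0.15, cold_factor: float = 0.5,
                   hot_factor: float = 1.25, cold_angle_deg: float = 30.0
                   ) -> list[dict]:
    """Classify the field pattern around each discrete fat inclusion.

    Current bypasses a poorly conducting inclusion: the exterior field
    collapses where the current would enter and exit (boundary normal
    aligned with the local current direction -> 'cold points') and is
    enhanced on the laterally oriented boundary ('hot points').  For
    each fat blob/slab, boundary samples at a small exterior ``offset``
    (mm) are compared against a far-field reference (median |E| on a
    standoff ring) and classified:

    * COLD: |E| < cold_factor * reference and normal within
      ``cold_angle_deg`` of the current direction,
    * HOT:  |E| > hot_factor * reference on a laterally oriented
      boundary (normal more than 60 degrees from the current).

    The reference for a boundary sample is the median |E| over a shell
    of points at the same distance from the electrode tip, which
    removes the radial decay of the source field and leaves the
    inclusion's perturbation.  (In a uniform applied field the shell
    median reduces to the unperturbed field.)

    Returns a list of dicts with keys ``r_mm``, ``z_mm``, ``type``,
    ``E_Vcm``, ``region``; empty if the map has no fat inclusions.
    """
    tmap = tmap or sol.mesh.tissue_map
    inclusions = tmap.fat_inclusions()
    if not inclusions:
        return []
    interp = _field_interpolator(sol)
    # nodal current-density direction field
    mesh = sol.mesh
    Jr = mesh.node_grid(sol.nodal_average(sol.sigma * sol.E_vec[:, 0]))
    Jz = mesh.node_grid(sol.nodal_average(sol.sigma * sol.E_vec[:, 1]))
    r_mm = mesh.r_lines / MM
    z_mm = mesh.z_lines / MM
    j_interp = RegularGridInterpolator(
        (r_mm, z_mm), np.stack([Jr, Jz], axis=-1),
        bounds_error=False, fill_value=0.0)

    out: list[dict] = []
    for reg in inclusions:
        poly = reg.polygon
        ring = poly.exterior
        n_samples = max(32, int(ring.length / 0.1))
        ts = np.linspace(0.0, ring.length, n_samples, endpoint=False)
        pts = np.array([ring.interpolate(t).coords[0] for t in ts])
        # outward normals from the tangent (ring orientation handled by test)
        tang = np.gradient(pts, axis=0)
        tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
        normals = np.column_stack([tang[:, 1], -tang[:, 0]])
        probe = pts + 0.05 * normals
        inside = shapely.contains_xy(poly, probe[:, 0], probe[:, 1])
        normals[inside] *= -1.0

        samples = pts + offset * normals
        keep = samples[:, 0] >= 0.0
        samples, normals_k, pts_k = samples[keep], normals[keep], pts[keep]
        E_loc = interp(samples)

        # per-sample reference: median |E| on the matched-distance shell
        # around the electrode tip, restricted to the tissue half-plane
        tip = np.array([0.0, tmap.spec.tip_z])
        dist = np.linalg.norm(samples - tip, axis=1)
        theta = np.linspace(0.0, np.pi, 64)
        E_ref = np.empty(len(samples))
        for i, R in enumerate(dist):
            shell = tip + R * np.column_stack([np.sin(theta), np.cos(theta)])
            ok = (shell[:, 0] >= 0.0) & (shell[:, 1] > 0.2)
            vals = interp(shell[ok])
            vals = vals[np.isfinite(vals) & (vals > 0)]
            E_ref[i] = float(np.median(vals)) if len(vals) else np.nan

        J_loc = j_interp(samples)
        J_dir = J_loc / np.maximum(
            np.linalg.norm(J_loc, axis=1, keepdims=True), 1e-30)
        cosang = np.abs(np.einsum("ij,ij->i", normals_k, J_dir))
        ang = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))

        cold = (E_loc < cold_factor * E_ref) & (ang < cold_angle_deg)
        hot = (E_loc > hot_factor * E_ref) & (ang > 60.0)
        for mask, kind in ((cold, "COLD"), (hot, "HOT")):
            for p, e in zip(pts_k[mask], E_loc[mask]):
                out.append({"r_mm": float(p[0]), "z_mm": float(p[1]),
                            "type": kind, "E_Vcm": float(e) * VCM_PER_VM,
                            "region": reg.name})
    return out
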