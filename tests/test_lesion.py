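"""Isoline extraction, lesion metrics, axis profiles, hot/cold points."""

import numpy as np
import pytest

from pfafield import (FieldSolution, axis_profile, build_model,
                      extract_isoline, generate_mesh, hotcold_points,
                      interface_flux_continuity, lesion_size)
from conftest import SPHERE

MM = 1e-3


@pytest.fixture(scope="module")
def radial_field_solution():
    """Synthetic point-source-like field |E| = c / R^2 centered at the
    origin, with c chosen so the 1000 V/cm level sits at R = 3 mm."""
    mesh = generate_mesh(build_model("A"))
    c = 1e5 * (3.0 * MM) ** 2  # V*m
    cent = mesh.centroids()
    R2 = np.maximum(cent[:, 0] ** 2 + cent[:, 1] ** 2, (0.05 * MM) ** 2)
    E_mag = c / R2
    ux = cent[:, 0] / np.sqrt(R2)
    uz = cent[:, 1] / np.sqrt(R2)
    E_vec = np.column_stack([E_mag * ux, E_mag * uz])
    return FieldSolution(
        mesh=mesh, phi=np.zeros(mesh.n_nodes), E_vec=E_vec, E_mag=E_mag,
        sigma=np.full(len(E_mag), 0.5), V_applied=1.0, I_delivered=1.0,
        I_ground=1.0, picard_iters=1, residual=0.0)


def test_radial_field_isoline_and_metrics(radial_field_solution):
    """Closed-form superlevel set: depth 3 mm, surface width 6 mm, and
    the isoline lies on the R = 3 mm arc."""
    met = lesion_size(radial_field_solution, threshold=1000.0)
    assert met.depth == pytest.approx(3.0, rel=0.01)
    assert met.surface_width == pytest.approx(6.0, rel=0.01)
    pts = np.vstack(met.isoline)
    R = np.hypot(pts[:, 0], pts[:, 1])
    arc = R > 2.0  # exclude the segments hugging the electrode boundary
    assert arc.any()
    assert np.abs(R[arc] - 3.0).max() < 0.03


def test_threshold_above_maximum_gives_empty_lesion(sol_A22):
    met = lesion_size(sol_A22, threshold=1e6)
    assert met.depth == 0.0 and met.surface_width == 0.0
    assert met.isoline == []
    assert extract_isoline(sol_A22, threshold=1e6) == []


def test_wall_lesion_dominant_component(sol_A22):
    """Homogeneous wall at 22 A: one dominant lesion around the
    electrode.  Any detached superlevel pocket lives in the epicardial
    fat band (where the field rebounds) and is excluded from depth."""
    met = lesion_size(sol_A22)
    assert met.depth > 2.0 and met.surface_width > 6.0
    assert met.depth < 7.0  # lesion proper stays in the myocardium
    assert not met.clamped_to_fat
    if met.n_satellites:
        pts = np.vstack(met.isoline)
        assert pts[:, 1].max() < 7.0  # main isoline excludes the pocket


def test_resampling_refinement_stability(sol_A22):
    m1 = lesion_size(sol_A22, h=0.025)
    m2 = lesion_size(sol_A22, h=0.0125)
    assert m2.depth == pytest.approx(m1.depth, rel=0.01)
    assert m2.surface_width == pytest.approx(m1.surface_width, rel=0.01)


def test_axis_profile_monotone_and_fat_peak(sol_A22):
    """Potential falls monotonically along the axis; |E| rebounds inside
    the poorly conducting epicardial fat band, exceeding the myocardial
    value 1 mm shallower."""
    prof = axis_profile(sol_A22)
    dphi = np.diff(prof.phi_V.values)
    assert (dphi <= 1e-6 * sol_A22.V_applied).all()
    assert prof.phi_V.iloc[0] == pytest.approx(sol_A22.V_applied, rel=1e-6)
    E = lambda z: np.interp(z, prof.z_mm, prof.E_Vcm)
    assert E(7.5) > E(6.5)


def test_interface_conditions_fat_myocardium(sol_A22):
    """sigma*E_n continuous and E_t continuous across the epicardial
    fat/myocardium interface (to discretization accuracy)."""
    res = interface_flux_continuity(sol_A22, z_interface=7.0, r_probe=1.0)
    assert res["sigma_En_ratio"] == pytest.approx(1.0, abs=0.05)
    assert res["Et_ratio"] == pytest.approx(1.0, abs=0.05)


def test_inclusion_cold_poles_hot_equator(inclusion_solution):
    """Current bypasses a poorly conducting sphere: field collapses at
    the poles (entry/exit) and is enhanced at the equator."""
    sol, sphere_map = inclusion_solution
    a, sm, sf, L, V = (SPHERE["a"], SPHERE["sigma_m"], SPHERE["sigma_f"],
                       SPHERE["L"], SPHERE["V"])
    zc = L / 2.0
    pts = hotcold_points(sol, sphere_map)
    cold = [p for p in pts if p["type"] == "COLD"]
    hot = [p for p in pts if p["type"] == "HOT"]
    assert cold and hot
    for p in cold:  # poles: on the axis at z = zc -/+ a
        assert abs(abs(p["z_mm"] - zc) - a) < 0.15 * a
        assert p["r_mm"] < 0.3 * a
    for p in hot:  # equatorial band
        assert abs(p["z_mm"] - zc) < 0.3 * a

    # exterior equatorial enhancement: E_z = E0 * (1 + beta * a^3/rho^3)
    E0 = V / (L * MM) * 1e-2  # V/cm
    beta = (sm - sf) / (2.0 * sm + sf)
    rho = a + 0.15  # classifier sampling offset
    expected = E0 * (1.0 + beta * (a / rho) ** 3)
    eq = [p["E_Vcm"] for p in hot if abs(p["z_mm"] - zc) < 0.15]
    assert np.mean(eq) == pytest.approx(expected, rel=0.03)


def test_fat_slab_cold_shadow_and_hot_rim(sol_D22):
    """Fat deposition in the scar: cold points at the current exit below
    the dominant slab, hot points lateral to its rim."""
    pts = hotcold_points(sol_D22)
    slab = [p for p in pts if p["region"] == "fat_slab"]
    scar = sol_D22.mesh.tissue_map.scar
    cold = [p for p in slab if p["type"] == "COLD"]
    hot = [p for p in slab if p["type"] == "HOT"]
    assert cold and hot
    # at least one cold point on the deep (exit) face of the slab
    assert any(abs(p["z_mm"] - scar.main_fat_slab_bottom) < 0.1 for p in cold)
    # hot points lateral: outboard of most of the slab
    assert all(p["r_mm"] > 2.0 for p in hot)


def test_no_inclusions_gives_empty_list(sol_A22):
    assert hotcold_points(sol_A22) == []
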