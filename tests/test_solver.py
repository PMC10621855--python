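"""Field solver: analytic oracles, conservation, nonlinear convergence."""

import numpy as np
import pytest

from pfafield import (TissueLabel, TissueProperties, axis_profile,
                      solve_at_current, solve_at_voltage)
from conftest import HEMI, SPHERE

MM = 1e-3


# --- hemispherical-electrode oracle ------------------------------------

def hemi_exact_current():
    a, Rg, sig, V = (HEMI["a"] * MM, HEMI["R_ground"] * MM,
                     HEMI["sigma"], HEMI["V"])
    return 2.0 * np.pi * sig * V / (1.0 / a - 1.0 / Rg)


def hemi_exact_phi(R_mm):
    a, Rg, V = HEMI["a"], HEMI["R_ground"], HEMI["V"]
    return V * (1.0 / R_mm - 1.0 / Rg) / (1.0 / a - 1.0 / Rg)


def test_hemisphere_current_matches_closed_form(hemisphere_solution):
    """Concentric-hemisphere conductance I = 2*pi*sigma*V / (1/a - 1/Rg)."""
    I = hemisphere_solution.I_delivered
    assert I == pytest.approx(hemi_exact_current(), rel=0.02)


def test_hemisphere_potential_profile(hemisphere_solution):
    """phi(R) ~ 1/R between electrode and ground, within 3%."""
    prof = axis_profile(hemisphere_solution, z_max=10.0)
    for R in (4.0, 5.0, 6.0, 8.0, 10.0):
        phi = np.interp(R, prof.z_mm, prof.phi_V)
        assert phi == pytest.approx(hemi_exact_phi(R), rel=0.03)


# --- insulating-sphere inclusion oracle --------------------------------

def test_inclusion_interior_field(inclusion_solution):
    """Interior field of a sphere in a uniform field: uniform, equal to
    3*sigma_m/(2*sigma_m + sigma_f) * E0."""
    sol, _ = inclusion_solution
    a, sm, sf, L, V = (SPHERE["a"], SPHERE["sigma_m"], SPHERE["sigma_f"],
                       SPHERE["L"], SPHERE["V"])
    E0 = V / (L * MM)
    cent = sol.mesh.centroids() / MM
    zc = L / 2.0
    inside = (cent[:, 0] ** 2 + (cent[:, 1] - zc) ** 2) <= (0.6 * a) ** 2
    E_in = sol.E_mag[inside]
    expected = 3.0 * sm / (2.0 * sm + sf) * E0
    assert E_in.mean() == pytest.approx(expected, rel=0.02)
    assert E_in.std() / E_in.mean() < 0.02  # interior uniformity


# --- conservation, linearity, monotonicity -----------------------------

def test_charge_conservation(sol_A22):
    """Electrode-side and ground-side fluxes agree (discrete conservation)."""
    assert abs(sol_A22.I_delivered - sol_A22.I_ground) \
        <= 0.005 * abs(sol_A22.I_delivered)


def test_linear_scaling_of_solution(mesh_A):
    """With sigma0 == sigma1 everywhere the problem is linear: doubling
    the voltage doubles the potential nodewise."""
    lin = TissueProperties(sigmas={
        lab.name: (0.5, 0.5) for lab in TissueLabel})
    s1 = solve_at_voltage(mesh_A, lin, 1000.0)
    s2 = solve_at_voltage(mesh_A, lin, 2000.0)
    assert s1.picard_iters == 1
    used = np.abs(s2.phi) > 0
    assert np.allclose(s2.phi[used], 2.0 * s1.phi[used], rtol=1e-8)


def test_linear_medium_current_match(mesh_A):
    """In a linear medium I = G*V, so current matching needs one scaling
    step: V = I_target / G."""
    lin = TissueProperties(sigmas={
        lab.name: (0.5, 0.5) for lab in TissueLabel})
    ref = solve_at_voltage(mesh_A, lin, 1000.0)
    G = ref.I_delivered / 1000.0
    sol = solve_at_current(mesh_A, lin, 20.0)
    assert sol.I_delivered == pytest.approx(20.0, rel=1e-3)
    assert sol.V_applied == pytest.approx(20.0 / G, rel=1e-3)


def test_picard_converges_on_nonlinear_wall(sol_A22):
    assert sol_A22.picard_iters < 50
    assert sol_A22.residual < 1e-4


def test_current_voltage_curve_monotone(mesh_A, props):
    """sigma nondecreasing in E makes I(V) strictly increasing."""
    Is = [solve_at_voltage(mesh_A, props, V).I_delivered
          for V in (1000.0, 2000.0, 3000.0)]
    assert Is[0] < Is[1] < Is[2]


def test_current_matching_contract(sol_A22):
    assert abs(sol_A22.I_delivered - 22.0) / 22.0 < 1e-3
    # applied voltage on the order of 2 kV
    assert 1000.0 < sol_A22.V_applied < 3000.0


def test_invalid_inputs(mesh_A, props):
    with pytest.raises(ValueError):
        solve_at_voltage(mesh_A, props, -5.0)
    with pytest.raises(ValueError):
        solve_at_current(mesh_A, props, 0.0)
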