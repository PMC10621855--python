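"""Shared fixtures: meshes and converged solutions reused across tests.

Nonlinear solves are the expensive part of the suite, so the reference
solutions (model A and D at 22 A, the full model/current sweep, and the
two analytic oracle configurations) are computed once per session.
"""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import Point

from pfafield import (GeometrySpec, RunConfig, ScarSpec, TissueLabel,
                      TissueMap, TissueProperties, Region, build_model,
                      generate_mesh, run_experiment, solve_at_current,
                      solve_at_voltage, tensor_mesh)

# analytic oracle parameters (mm, S/m, V)
HEMI = dict(a=3.0, R_ground=11.0, sigma=0.5, V=100.0, h=0.05, box=12.0)
SPHERE = dict(a=2.0, sigma_m=0.6, sigma_f=0.08, L=24.0, R_box=12.0,
              h=0.1, V=100.0)


@pytest.fixture(scope="session")
def props():
    return TissueProperties()


@pytest.fixture(scope="session")
def mesh_A():
    return generate_mesh(build_model("A"))


@pytest.fixture(scope="session")
def sol_A22(mesh_A, props):
    return solve_at_current(mesh_A, props, 22.0)


@pytest.fixture(scope="session")
def sol_D22(props):
    mesh = generate_mesh(build_model("D", scar=ScarSpec(), seed=1))
    return solve_at_current(mesh, props, 22.0)


@pytest.fixture(scope="session")
def experiment_df():
    """Full default sweep: six wall models x three delivered currents."""
    return run_experiment(RunConfig(seed=1))


@pytest.fixture(scope="session")
def hemisphere_solution():
    """Hemispherical electrode of radius a in a uniform medium, grounded
    on a concentric hemisphere: phi and I have closed forms."""
    a, Rg, sig, V, h, boxsz = (HEMI["a"], HEMI["R_ground"], HEMI["sigma"],
                               HEMI["V"], HEMI["h"], HEMI["box"])
    lines = np.arange(0.0, boxsz + 1e-9, h)
    prp = TissueProperties(
        sigmas={lab.name: (sig, sig) for lab in TissueLabel})

    def label_fn(r, z):
        out = np.full(r.shape, int(TissueLabel.MYOCARDIUM))
        out[r ** 2 + z ** 2 <= (a + h / 2) ** 2] = int(TissueLabel.ELECTRODE)
        return out

    mesh = tensor_mesh(
        lines, lines, label_fn,
        lambda r, z: r ** 2 + z ** 2 <= (a + h / 2) ** 2 + 1e-12,
        lambda r, z: r ** 2 + z ** 2 >= (Rg - h / 2) ** 2 - 1e-12)
    return solve_at_voltage(mesh, prp, V)


@pytest.fixture(scope="session")
def inclusion_solution():
    """Poorly conducting sphere on the axis of a uniform applied field."""
    a, sm, sf, L, Rb, h, V = (SPHERE["a"], SPHERE["sigma_m"],
                              SPHERE["sigma_f"], SPHERE["L"],
                              SPHERE["R_box"], SPHERE["h"], SPHERE["V"])
    zl = np.arange(0.0, L + 1e-9, h)
    rl = np.arange(0.0, Rb + 1e-9, h)
    sig = {lab.name: (sm, sm) for lab in TissueLabel}
    sig["FAT"] = (sf, sf)
    prp = TissueProperties(sigmas=sig)
    zc = L / 2

    def label_fn(r, z):
        out = np.full(r.shape, int(TissueLabel.MYOCARDIUM))
        out[r ** 2 + (z - zc) ** 2 <= a ** 2] = int(TissueLabel.FAT)
        return out

    mesh = tensor_mesh(rl, zl, label_fn,
                       lambda r, z: np.isclose(z, 0.0),
                       lambda r, z: np.isclose(z, L))
    sol = solve_at_voltage(mesh, prp, V)
    sphere_map = TissueMap(
        spec=GeometrySpec(), model_id="A",
        regions=[Region(TissueLabel.FAT,
                        Point(0.0, zc).buffer(a, quad_segs=64),
                        "blob", "sphere")])
    return sol, sphere_map
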