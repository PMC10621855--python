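"""Axisymmetric quasi-static field solver with field-dependent conductivity.

Solves the current-conservation (generalized Laplace) equation

    div(sigma(E) grad(phi)) = 0

in the (r, z) half-plane with the 2*pi*r axisymmetric weighting, using
piecewise-linear triangles.  Boundary conditions: phi = V on the
electrode surface, phi = 0 on the outer boundaries (monopolar return),
natural zero-flux on the symmetry axis and the insulated shaft.

The conductivity nonlinearity (electroporation sigmoid) is resolved by
damped Picard iteration: solve the linear problem, update the
per-element field magnitude, relax the per-element conductivity toward
sigma(|E|), repeat until the relative conductivity change stalls below
tolerance.  The electrode voltage delivering a target current is found
by a secant iteration on the (monotone, nearly linear) I-V curve.

Delivered current is computed by the volume-consistent flux: the
assembled stiffness operator applied to the solution, summed over the
electrode's Dirichlet nodes.  By discrete conservation this matches the
ground-boundary flux to solver precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .conductivity import TissueProperties, sigma_of_E
from .geometry import TissueLabel
from .mesh import Mesh

__all__ = ["SolverSettings", "FieldSolution", "solve_at_voltage",
           "solve_at_current", "ConvergenceError"]

log = logging.getLogger("pfafield.solver")


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolverSettings:
    picard_tol: float = 1e-4
    picard_max_iter: int = 50
    damping: float = 0.5
    current_tol: float = 1e-3
    current_max_iter: int = 25

    def __post_init__(self) -> None:
        if not (0 < self.damping <= 1):
            raise ValueError("damping must be in (0, 1]")
        if self.picard_tol <= 0 or self.current_tol <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass
class FieldSolution:
    """Converged field on a mesh (SI units)."""

    mesh: Mesh
    phi: np.ndarray        # (n_nodes,) V; 0 on inactive nodes
    E_vec: np.ndarray      # (n_elem, 2) V/m, zero on inactive elements
    E_mag: np.ndarray      # (n_elem,) V/m
    sigma: np.ndarray      # (n_elem,) S/m converged
    V_applied: float
    I_delivered: float     # A, electrode-side flux
    I_ground: float        # A, ground-side flux (sign-matched)
    picard_iters: int
    residual: float

    @property
    def J_mag(self) -> np.ndarray:
        """Current density magnitude per element (A/m^2)."""
        return self.sigma * self.E_mag

    def nodal_average(self, elem_values: np.ndarray,
                      elem_mask: np.ndarray | None = None) -> np.ndarray:
        """Area-weighted average of an element field onto nodes.

        Inactive elements are excluded, so nodal values on material/device
        surfaces are one-sided into the conductive domain.  With
        ``elem_mask`` the average is restricted further (e.g. to one
        tissue), yielding one-sided values on material interfaces where
        the true field is discontinuous; nodes touching no selected
        element are NaN.
        """
        mesh = self.mesh
        sel = mesh.active if elem_mask is None else (mesh.active & elem_mask)
        tri = mesh.elements[sel]
        vals = np.asarray(elem_values)[sel]
        p = mesh.nodes
        d1 = p[tri[:, 1]] - p[tri[:, 0]]
        d2 = p[tri[:, 2]] - p[tri[:, 0]]
        area = 0.5 * np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
        num = np.zeros(mesh.n_nodes)
        den = np.zeros(mesh.n_nodes)
        for k in range(3):
            np.add.at(num, tri[:, k], area * vals)
            np.add.at(den, tri[:, k], area)
        out = np.full(mesh.n_nodes, np.nan)
        nz = den > 0
        out[nz] = num[nz] / den[nz]
        if elem_mask is None:
            out[~nz] = 0.0
        return out


class _Assembler:
    """Precomputed element geometry for fast repeated stiffness assembly."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        tri = mesh.elements
        p = mesh.nodes
        x = p[tri, 0]  # (ne, 3) r
        y = p[tri, 1]  # (ne, 3) z
        # P1 gradient coefficients: grad(N_k) = (b_k, c_k) / (2A)
        b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0],
                      y[:, 0] - y[:, 1]], axis=1)
        c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2],
                      x[:, 1] - x[:, 0]], axis=1)
        area2 = x[:, 0] * b[:, 0] + x[:, 1] * b[:, 1] + x[:, 2] * b[:, 2]
        self.area = 0.5 * np.abs(area2)
        self.b = b
        self.c = c
        r_bar = x.mean(axis=1)
        # geometric local stiffness (without sigma): 2*pi*r_bar/(4A) (bb^T+cc^T)
        w = (2.0 * np.pi * r_bar / (4.0 * self.area))[:, None, None]
        self.G = w * (b[:, :, None] * b[:, None, :] +
                      c[:, :, None] * c[:, None, :])
        self.G[~mesh.active] = 0.0
        self.rows = np.repeat(tri, 3, axis=1).ravel()
        self.cols = np.tile(tri, (1, 3)).ravel()
        self.n = mesh.n_nodes

    def stiffness(self, sigma_e: np.ndarray) -> sp.csr_matrix:
        data = (sigma_e[:, None, None] * self.G).ravel()
        K = sp.coo_matrix((data, (self.rows, self.cols)),
                          shape=(self.n, self.n))
        return K.tocsr()

    def gradient(self, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-element E = -grad(phi); zero on inactive elements."""
        tri = self.mesh.elements
        ph = phi[tri]
        inv2A = 1.0 / (2.0 * self.area)
        Er = -np.einsum("ek,ek->e", self.b, ph) * inv2A
        Ez = -np.einsum("ek,ek->e", self.c, ph) * inv2A
        Er[~self.mesh.active] = 0.0
        Ez[~self.mesh.active] = 0.0
        return Er, Ez


def _linear_solve(asm: _Assembler, mesh: Mesh, sigma_e: np.ndarray,
                  V_applied: float) -> tuple[np.ndarray, float, float]:
    """One linear solve at fixed per-element sigma; returns (phi, I_elec, I_gnd)."""
    n = mesh.n_nodes
    K = asm.stiffness(sigma_e)
    used = np.zeros(n, dtype=bool)
    used[np.unique(mesh.elements[mesh.active])] = True
    dir_mask = np.zeros(n, dtype=bool)
    dir_mask[mesh.electrode_nodes] = True
    dir_mask[mesh.ground_nodes] = True
    free = used & ~dir_mask
    if not mesh.ground_nodes.size:
        raise ConvergenceError("no ground boundary: singular system")

    phi = np.zeros(n)
    phi[mesh.electrode_nodes] = V_applied
    free_idx = np.flatnonzero(free)
    rhs = -K[free_idx, :] @ phi
    K_ff = K[free_idx, :][:, free_idx].tocsc()
    lu = splu(K_ff)
    phi[free_idx] = lu.solve(rhs)

    flux = K @ phi
    I_elec = float(flux[mesh.electrode_nodes].sum())
    I_gnd = float(-flux[mesh.ground_nodes].sum())
    return phi, I_elec, I_gnd


def solve_at_voltage(mesh: Mesh, props: TissueProperties, V_applied: float,
                     settings: SolverSettings | None = None,
                     sigma_init: np.ndarray | None = None,
                     _asm: _Assembler | None = None) -> FieldSolution:
    """Solve the nonlinear problem at a fixed electrode voltage."""
    if V_applied <= 0:
        raise ValueError("V_applied must be > 0")
    settings = settings or SolverSettings()
    asm = _asm or _Assembler(mesh)

    lab = mesh.elem_label
    s0 = props.sigma0_array()[lab]
    s1 = props.sigma1_array()[lab]
    nonlinear = bool(np.any(s1[mesh.active] > s0[mesh.active]))
    sigma_e = s0.copy() if sigma_init is None else sigma_init.copy()

    phi = np.zeros(mesh.n_nodes)
    residual = np.inf
    iters = 0
    for iters in range(1, settings.picard_max_iter + 1):
        phi, I_elec, I_gnd = _linear_solve(asm, mesh, sigma_e, V_applied)
        Er, Ez = asm.gradient(phi)
        E_mag = np.hypot(Er, Ez)
        sigma_new = sigma_of_E(lab, E_mag, props)
        sigma_next = sigma_e + settings.damping * (sigma_new - sigma_e)
        act = mesh.active & (sigma_e > 0)
        residual = float(np.max(np.abs(sigma_next - sigma_e)[act]
                                / sigma_e[act])) if act.any() else 0.0
        sigma_e = sigma_next
        log.debug("picard %d: residual %.3e, I %.4f A", iters, residual, I_elec)
        if residual < settings.picard_tol or not nonlinear:
            break
    else:
        raise ConvergenceError(
            f"Picard stalled at residual {residual:.3e} after "
            f"{settings.picard_max_iter} iterations")

    # final consistent solve with the converged conductivity
    phi, I_elec, I_gnd = _linear_solve(asm, mesh, sigma_e, V_applied)
    Er, Ez = asm.gradient(phi)
    E_mag = np.hypot(Er, Ez)
    return FieldSolution(mesh=mesh, phi=phi,
                         E_vec=np.column_stack([Er, Ez]), E_mag=E_mag,
                         sigma=sigma_e, V_applied=float(V_applied),
                         I_delivered=I_elec, I_ground=I_gnd,
                         picard_iters=iters, residual=residual)


def solve_at_current(mesh: Mesh, props: TissueProperties, I_target: float,
                     settings: SolverSettings | None = None,
                     V_guess: float = 2000.0) -> FieldSolution:
    """Find the electrode voltage that delivers ``I_target`` amperes.

    Secant iteration on the monotone I-V characteristic, warm-starting
    each nonlinear solve from the previous conductivity state.
    """
    if I_target <= 0:
        raise ValueError("I_target must be > 0")
    settings = settings or SolverSettings()
    asm = _Assembler(mesh)

    V = float(V_guess)
    sol = solve_at_voltage(mesh, props, V, settings, _asm=asm)
    history = [(V, sol.I_delivered)]
    for k in range(settings.current_max_iter):
        err = (sol.I_delivered - I_target) / I_target
        log.debug("current iter %d: V=%.1f I=%.3f err=%.2e",
                  k, V, sol.I_delivered, err)
        if abs(err) < settings.current_tol:
            return sol
        if len(history) >= 2:
            (V0, I0), (V1, I1) = history[-2], history[-1]
            if I1 == I0:
                raise ConvergenceError("flat I-V characteristic")
            if (I1 - I0) * (V1 - V0) < 0:
                raise ConvergenceError("non-monotone I(V) detected")
            V_new = V1 + (I_target - I1) * (V1 - V0) / (I1 - I0)
        else:
            V_new = V * I_target / sol.I_delivered
        if V_new <= 0:
            V_new = 0.5 * V
        sol = solve_at_voltage(mesh, props, V_new, settings,
                               sigma_init=sol.sigma, _asm=asm)
        history.append((V_new, sol.I_delivered))
        V = V_new
    raise ConvergenceError(
        f"current matching did not reach {I_target} A within "
        f"{settings.current_max_iter} iterations (last I="
        f"{sol.I_delivered:.3f} A)")
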