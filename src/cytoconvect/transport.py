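"""Steady advection–diffusion of a passive concentration on a computed flow.

Solves  ∇·(u C) = D ∇²C  for a normalized species concentration C ∈ [0, 1]
with C = 1 on a chosen source wall and C = 0 on the opposite (absorbing)
wall.  At diffusivities down to 1e-5 μm²/s the cell Péclet number is large,
so the discretization combines SUPG streamline stabilization with a
residual-based discontinuity-capturing viscosity (a few fixed-point
iterations) to keep the field within its boundary bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import spsolve

from .errors import ConfigurationError, InvalidInputError
from .fem import P1Basis
from .flow import UM, FlowSolution, _apply_dirichlet
from .meshing import Mesh

__all__ = ["ConcentrationField", "solve_concentration"]


@dataclass
class ConcentrationField:
    """Normalized steady concentration (C ∈ [0,1] up to stabilization error)."""

    mesh: Mesh
    c: np.ndarray
    diffusivity_um2_s: float
    source_wall: str

    @property
    def values(self) -> np.ndarray:
        return self.c


def _opposite_wall(source_wall: str) -> str:
    base = source_wall.split(":")[0]
    if base == "w1":
        return "w2"
    if base == "w2":
        return "w1"
    raise InvalidInputError(f"source wall must be w1 or w2, got {source_wall!r}")


def solve_concentration(
    flow: FlowSolution,
    mesh: Mesh,
    D: float,
    source_wall: str = "w1",
    n_sc_iterations: int = 8,
    shock_capturing: bool = True,
) -> ConcentrationField:
    """Solve the steady concentration equation on a converged flow field.

    Parameters
    ----------
    flow : FlowSolution
        Converged velocity field; must live on ``mesh``.
    mesh : Mesh
    D : float
        Molecular diffusivity in μm² s⁻¹ (> 0).
    source_wall : str
        ``"w1"`` (material entering from outside the cell) or ``"w2"``
        (material originating at the nucleus); C = 1 there, C = 0 on the
        opposite wall.  Heat-patch facets count as part of the nucleus wall.
    n_sc_iterations : int
        Fixed-point iterations for the nonlinear discontinuity-capturing
        term (ignored when ``shock_capturing`` is False).
    """
    if not (np.isfinite(D) and D > 0):
        raise InvalidInputError(f"diffusivity must be > 0, got {D!r}")
    if flow.mesh is not mesh and (
        flow.u.shape[0] != mesh.n_nodes
        or not np.array_equal(flow.mesh.points, mesh.points)
    ):
        raise ConfigurationError("flow solution does not match the mesh")
    D_si = D * UM**2  # μm²/s -> m²/s

    basis = P1Basis(mesh.points * UM, mesh.cells)
    u_elem = flow.u[basis.cells].mean(axis=1)

    # Dirichlet data: source wall = 1, opposite wall (incl. patches on w2) = 0
    sink_wall = _opposite_wall(source_wall)

    def wall_nodes(base: str) -> np.ndarray:
        nodes = [mesh.nodes_with_tag(base)]
        if base == "w2":
            for tid, name in mesh.tag_names.items():
                if name.split(":")[0] not in ("w1", "w2"):
                    nodes.append(
                        np.unique(mesh.boundary_facets[mesh.facet_tags == tid])
                    )
        return np.unique(np.concatenate(nodes))

    src = wall_nodes(source_wall.split(":")[0])
    snk = wall_nodes(sink_wall)
    idx = np.concatenate([src, snk])
    vals = np.concatenate([np.ones(len(src)), np.zeros(len(snk))])

    un = np.linalg.norm(u_elem, axis=1)
    h = basis.h
    tau = 1.0 / np.sqrt((2.0 * un / h) ** 2 + 9.0 * (4.0 * D_si / h**2) ** 2)

    K = basis.stiffness()
    A0 = D_si * K + basis.advection(u_elem) + basis.supg(u_elem, tau)
    rhs = np.zeros(basis.n_nodes)
    A_d, rhs_d = _apply_dirichlet(A0.tocsr(), rhs.copy(), idx, vals)
    c = spsolve(A_d.tocsc(), rhs_d)

    if shock_capturing:
        # residual-based isotropic artificial diffusion, capped at the
        # first-order upwind level; lagged (fixed-point) in c
        for _ in range(n_sc_iterations):
            gc = np.einsum("eid,ei->ed", basis.grads, c[basis.cells])
            gnorm = np.linalg.norm(gc, axis=1)
            resid = np.abs(np.einsum("ed,ed->e", u_elem, gc))  # |u·∇c| (P1: ∇²c=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                nu_sc = 0.5 * h * resid / np.where(gnorm > 0, gnorm, 1.0)
            nu_sc = np.minimum(nu_sc, 0.5 * h * un)
            A = A0 + basis.stiffness(nu_sc)
            A_d, rhs_d = _apply_dirichlet(A.tocsr(), rhs.copy(), idx, vals)
            c_new = spsolve(A_d.tocsc(), rhs_d)
            if np.max(np.abs(c_new - c)) < 1e-10:
                c = c_new
                break
            c = c_new

    return ConcentrationField(
        mesh=mesh, c=c, diffusivity_um2_s=float(D), source_wall=source_wall
    )
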