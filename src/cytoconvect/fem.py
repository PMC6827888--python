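"""Vectorized P1 (linear simplex) finite-element operators.

All assembly routines return ``scipy.sparse`` matrices in CSR format and
work in either two or three dimensions.  Only the few operators the flow,
energy and transport equations need are provided: stiffness, mass,
advection, divergence/gradient coupling blocks, grad-div, and the
streamline (SUPG) and pressure (PSPG) stabilization terms built from
element-mean velocities.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix

__all__ = ["P1Basis"]


class P1Basis:
    """Precomputed geometry factors of a simplicial mesh.

    Parameters
    ----------
    points : ndarray (n_nodes, d)
        Node coordinates (any consistent length unit; the caller is
        responsible for using SI when assembling physical operators).
    cells : ndarray (n_elems, d+1)
    """

    def __init__(self, points: np.ndarray, cells: np.ndarray):
        self.points = np.asarray(points, dtype=float)
        self.cells = np.asarray(cells, dtype=int)
        self.dim = self.points.shape[1]
        d = self.dim
        p = self.points[self.cells]                      # (ne, d+1, d)
        E = p[:, 1:, :] - p[:, :1, :]                    # (ne, d, d)
        det = np.linalg.det(E)
        self.volumes = det / (2.0 if d == 2 else 6.0)
        if np.any(self.volumes <= 0):
            raise ValueError("mesh contains inverted elements")
        Einv = np.linalg.inv(E)                          # (ne, d, d)
        # gradients of barycentric functions: lambda_k (k=1..d) rows of Einv^T
        gk = np.transpose(Einv, (0, 2, 1))               # (ne, d, d)
        g0 = -gk.sum(axis=1, keepdims=True)
        self.grads = np.concatenate([g0, gk], axis=1)    # (ne, d+1, d)
        # longest edge per element
        nv = d + 1
        h = np.zeros(len(self.cells))
        for i in range(nv):
            for j in range(i + 1, nv):
                h = np.maximum(h, np.linalg.norm(p[:, i] - p[:, j], axis=1))
        self.h = h
        self.n_nodes = len(self.points)
        # index template for (d+1)x(d+1) element matrices
        rows = np.repeat(self.cells, nv, axis=1)         # (ne, nv*nv)
        cols = np.tile(self.cells, (1, nv))
        self._rows = rows.ravel()
        self._cols = cols.ravel()

    # -- helpers -------------------------------------------------------------

    def _to_csr(self, local: np.ndarray) -> csr_matrix:
        """local: (ne, nv, nv) element matrices -> global CSR."""
        return coo_matrix(
            (local.reshape(len(self.cells), -1).ravel(), (self._rows, self._cols)),
            shape=(self.n_nodes, self.n_nodes),
        ).tocsr()

    def element_mean(self, nodal: np.ndarray) -> np.ndarray:
        """Mean of a nodal field over each element's vertices."""
        return nodal[self.cells].mean(axis=1)

    # -- scalar operators -----------------------------------------------------

    def stiffness(self, coeff=1.0) -> csr_matrix:
        """(coeff ∇φi, ∇φj); ``coeff`` scalar or per-element array."""
        c = np.broadcast_to(np.asarray(coeff, dtype=float), self.volumes.shape)
        local = np.einsum(
            "e,eid,ejd->eij", c * self.volumes, self.grads, self.grads
        )
        return self._to_csr(local)

    def mass(self, coeff=1.0, lumped: bool = False) -> csr_matrix:
        """(coeff φi, φj) with the exact P1 formula ∫φiφj = V(1+δij)/((d+1)(d+2))."""
        nv = self.dim + 1
        c = np.broadcast_to(np.asarray(coeff, dtype=float), self.volumes.shape)
        if lumped:
            local = np.zeros((len(self.cells), nv, nv))
            idx = np.arange(nv)
            local[:, idx, idx] = (c * self.volumes / nv)[:, None]
            return self._to_csr(local)
        base = (np.ones((nv, nv)) + np.eye(nv)) / ((nv) * (nv + 1))
        local = (c * self.volumes)[:, None, None] * base[None, :, :]
        return self._to_csr(local)

    def advection(self, u_elem: np.ndarray, coeff=1.0) -> csr_matrix:
        """(coeff φi, ū·∇φj) with element-mean convecting velocity ``u_elem``."""
        nv = self.dim + 1
        c = np.broadcast_to(np.asarray(coeff, dtype=float), self.volumes.shape)
        udg = np.einsum("ed,ejd->ej", u_elem, self.grads)     # (ne, nv)
        local = (c * self.volumes / nv)[:, None, None] * udg[:, None, :]
        local = np.broadcast_to(local, (len(self.cells), nv, nv)).copy()
        return self._to_csr(local)

    def supg(self, u_elem: np.ndarray, tau: np.ndarray, coeff=1.0) -> csr_matrix:
        """Streamline term (tau coeff ū·∇φi, ū·∇φj)."""
        c = np.broadcast_to(np.asarray(coeff, dtype=float), self.volumes.shape)
        udg = np.einsum("ed,ejd->ej", u_elem, self.grads)
        local = np.einsum("e,ei,ej->eij", tau * c * self.volumes, udg, udg)
        return self._to_csr(local)

    def gradp_block(self, component: int) -> csr_matrix:
        """Pressure-gradient coupling  -(∂_a φi, φj): rows = velocity test
        functions of component ``a``, cols = pressure nodes.  Assembled via
        -(∇·v, p) integrated by parts onto P1 spaces exactly."""
        nv = self.dim + 1
        gi = self.grads[:, :, component]                      # (ne, nv)
        local = -(self.volumes / nv)[:, None, None] * gi[:, :, None]
        local = np.broadcast_to(local, (len(self.cells), nv, nv)).copy()
        return self._to_csr(local)

    def div_block(self, component: int, coeff=1.0) -> csr_matrix:
        """(coeff φi, ∂_a φj): rows = pressure test functions, cols = u_a."""
        nv = self.dim + 1
        c = np.broadcast_to(np.asarray(coeff, dtype=float), self.volumes.shape)
        gj = self.grads[:, :, component]
        local = (c * self.volumes / nv)[:, None, None] * gj[:, None, :]
        local = np.broadcast_to(local, (len(self.cells), nv, nv)).copy()
        return self._to_csr(local)

    def graddiv_block(self, a: int, b: int, coeff=1.0) -> csr_matrix:
        """(coeff ∂_a φi, ∂_b φj) — the (a, b) block of the grad-div term."""
        c = np.broadcast_to(np.asarray(coeff, dtype=float), self.volumes.shape)
        local = np.einsum(
            "e,ei,ej->eij", c * self.volumes, self.grads[:, :, a], self.grads[:, :, b]
        )
        return self._to_csr(local)

    def pspg_pressure(self, tau: np.ndarray) -> csr_matrix:
        """(tau ∇φi, ∇φj) — pressure-Laplacian stabilization block."""
        return self.stiffness(tau)

    def pspg_advection(self, component: int, u_elem: np.ndarray, tau: np.ndarray,
                       coeff=1.0) -> csr_matrix:
        """(tau coeff ∂_a φi, ū·∇φj): continuity-row coupling to u_a advection."""
        nv = self.dim + 1
        c = np.broadcast_to(np.asarray(coeff, dtype=float), self.volumes.shape)
        udg = np.einsum("ed,ejd->ej", u_elem, self.grads)
        local = np.einsum(
            "e,ei,ej->eij", tau * c * self.volumes, self.grads[:, :, component], udg
        )
        return self._to_csr(local)

    # -- right-hand sides ------------------------------------------------------

    def load_nodal(self, f_nodal: np.ndarray) -> np.ndarray:
        """(φi, f) for a P1 nodal field f (consistent mass action)."""
        return self.mass() @ f_nodal

    def grad_projection(self, f_elem: np.ndarray, tau: np.ndarray) -> np.ndarray:
        """(tau ∇φi, f̄) for an element-wise vector field (PSPG force term)."""
        rhs = np.zeros(self.n_nodes)
        contrib = np.einsum("e,eid,ed->ei", tau * self.volumes, self.grads, f_elem)
        np.add.at(rhs, self.cells.ravel(), contrib.ravel())
        return rhs

    def streamline_projection(self, u_elem, f_elem, tau, coeff=1.0) -> np.ndarray:
        """(tau coeff ū·∇φi, f̄) — SUPG test-function force term (scalar f per
        component handled by the caller)."""
        c = np.broadcast_to(np.asarray(coeff, dtype=float), self.volumes.shape)
        udg = np.einsum("ed,eid->ei", u_elem, self.grads)
        rhs = np.zeros(self.n_nodes)
        contrib = (tau * c * self.volumes * f_elem)[:, None] * udg
        np.add.at(rhs, self.cells.ravel(), contrib.ravel())
        return rhs
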