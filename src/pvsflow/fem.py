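"""Vectorized P1 finite-element kernels on axisymmetric triangle meshes.

Fields live on linear triangles in the meridional (r, z) plane; volume
integrals carry the axisymmetric measure 2*pi*r dr dz.  Meridional
gradients of P1 functions are element-wise constant; terms involving the
radius (hoop strains, the 1/r part of the divergence) are integrated with
the three-point edge-midpoint rule, which is exact for quadratics.

The kernels return scipy COO triplets or dense per-element blocks; the
solver modules assemble them into global sparse systems.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["TriGeometry", "assemble_coo", "edge_normal_weights"]

# shape functions at the edge-midpoint quadrature points (rows: points)
_NQ = np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5]])


class TriGeometry:
    """Per-element geometry of a P1 triangulation (vectorized).

    Attributes: ``area`` (E,), ``grads`` (E, 3, 2) gradients of the nodal
    basis, ``r_q`` (E, 3) radii at quadrature points, ``r_c`` (E,) centroid
    radii, ``w_q`` (E, 3) quadrature weights (area/3).
    """

    def __init__(self, nodes: np.ndarray, tris: np.ndarray):
        self.tris = tris
        p = nodes[tris]  # (E, 3, 2)
        self.p = p
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
        if np.any(det <= 0):
            bad = np.where(det <= 0)[0]
            raise ValueError(f"non-positive Jacobian in cells {bad[:10].tolist()}")
        self.area = 0.5 * det
        # gradients of barycentric coordinates
        g = np.empty((tris.shape[0], 3, 2))
        g[:, 0, 0] = (p[:, 1, 1] - p[:, 2, 1]) / det
        g[:, 0, 1] = (p[:, 2, 0] - p[:, 1, 0]) / det
        g[:, 1, 0] = (p[:, 2, 1] - p[:, 0, 1]) / det
        g[:, 1, 1] = (p[:, 0, 0] - p[:, 2, 0]) / det
        g[:, 2, 0] = (p[:, 0, 1] - p[:, 1, 1]) / det
        g[:, 2, 1] = (p[:, 1, 0] - p[:, 0, 0]) / det
        self.grads = g
        self.r_q = _NQ @ p[:, :, 0].T  # (3, E) -> transpose
        self.r_q = self.r_q.T
        self.z_q = (_NQ @ p[:, :, 1].T).T
        self.r_c = p[:, :, 0].mean(axis=1)
        self.w_q = np.repeat(self.area[:, None] / 3.0, 3, axis=1)
        self.NQ = _NQ

    # -- elementary blocks (E, 3, 3) -----------------------------------------

    def mass_blocks(self, weight=None, axisym: bool = True) -> np.ndarray:
        """int N_i N_j [2 pi r] dA, optionally scaled per element."""
        r = self.r_q if axisym else np.ones_like(self.r_q)
        fac = 2.0 * np.pi if axisym else 1.0
        blocks = fac * np.einsum("eq,qi,qj->eij", self.w_q * r, _NQ, _NQ)
        if weight is not None:
            blocks = blocks * np.asarray(weight)[:, None, None]
        return blocks

    def load_vector_blocks(self) -> np.ndarray:
        """int N_i 2 pi r dA, (E, 3)."""
        return 2.0 * np.pi * np.einsum("eq,qi->ei", self.w_q * self.r_q, _NQ)

    def stiffness_blocks(self, weight=None, axisym: bool = True) -> np.ndarray:
        """int grad(N_i).grad(N_j) [2 pi r] dA."""
        if axisym:
            scale = 2.0 * np.pi * self.area * self.r_c
        else:
            scale = self.area
        blocks = np.einsum("e,eia,eja->eij", scale, self.grads, self.grads)
        if weight is not None:
            blocks = blocks * np.asarray(weight)[:, None, None]
        return blocks

    def hoop_mass_blocks(self) -> np.ndarray:
        """int N_i N_j / r * 2 pi r dA = 2 pi int N_i N_j dA."""
        return 2.0 * np.pi * np.einsum("eq,qi,qj->eij", self.w_q, _NQ, _NQ)

    def inv_r_mass_blocks(self) -> np.ndarray:
        """int N_i N_j / r^2 * 2 pi r dA (hoop-hoop viscous/elastic term)."""
        return 2.0 * np.pi * np.einsum("eq,qi,qj->eij", self.w_q / self.r_q, _NQ, _NQ)

    def volume(self) -> float:
        """Total axisymmetric volume 2 pi int r dA."""
        return float(2.0 * np.pi * np.sum(self.w_q * self.r_q))


def assemble_coo(blocks: np.ndarray, rows_nodes: np.ndarray, cols_nodes: np.ndarray,
                 shape: tuple[int, int]) -> sp.csr_matrix:
    """Assemble (E, a, b) element blocks into a CSR matrix.

    ``rows_nodes``/``cols_nodes`` are (E, a) and (E, b) global dof indices.
    """
    E, a, b = blocks.shape
    rows = np.repeat(rows_nodes[:, :, None], b, axis=2).ravel()
    cols = np.repeat(cols_nodes[:, None, :], a, axis=1).ravel()
    return sp.coo_matrix((blocks.ravel(), (rows, cols)), shape=shape).tocsr()


def edge_normal_weights(nodes: np.ndarray, edges: np.ndarray, n_z: float) -> tuple[np.ndarray, np.ndarray]:
    """Weights of int_Gamma N_i (phi . n) 2 pi r dr on a constant-z boundary.

    ``edges`` are (E, 2) node pairs along the radial line; ``n_z`` is the
    z-component (+-1) of the outward normal.  Returns (node_ids, weights)
    such that the signed outflow through the boundary is
    sum(weights * v_z[node_ids]).
    """
    r1 = nodes[edges[:, 0], 0]
    r2 = nodes[edges[:, 1], 0]
    dr = r2 - r1
    w1 = 2.0 * np.pi * dr * (2.0 * r1 + r2) / 6.0
    w2 = 2.0 * np.pi * dr * (r1 + 2.0 * r2) / 6.0
    ids = np.concatenate([edges[:, 0], edges[:, 1]])
    w = n_z * np.concatenate([w1, w2])
    # combine duplicate node contributions
    uids, inv = np.unique(ids, return_inverse=True)
    acc = np.zeros(uids.shape[0])
    np.add.at(acc, inv, w)
    return uids, acc
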