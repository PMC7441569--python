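"""Compressible Saint-Venant-Kirchhoff (SVK) brain-tissue mechanics.

The brain section is an axisymmetric annulus R2 <= r <= R3 treated as a
compressible SVK solid in a total-Lagrangian setting: with deformation
gradient F = I + Grad(u), Green-Lagrange strain E = (F^T F - I)/2 and
second Piola-Kirchhoff stress S = lambda_s tr(E) I + 2 mu_s E, the Cauchy
stress is sigma = F S F^T / det(F).  An alternative strain measure
eps = F F^T - I (the left Cauchy-Green tensor minus identity, without the
1/2) is available behind ``strain="left_cg"`` for comparison; the
Green-Lagrange form is the standard SVK definition and the default.

Boundary conditions: tissue fixed at the outer radius r = R3; the deep face
(z = 0) is a roller (no axial displacement); the pial face (z = La) is
traction-free.  The inner face r = R2 carries the fluid traction.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from pvsflow.fem import TriGeometry, assemble_coo
from pvsflow.mesh import AxisymMesh, build_mesh
from pvsflow.parameters import ModelParameters, lame_lambda

__all__ = ["svk_stress", "SolidModel", "static_tissue_estimate", "lame_annulus_displacement"]


def svk_stress(F: np.ndarray, params: ModelParameters, strain: str = "green") -> np.ndarray:
    """Cauchy stress of the SVK material for deformation gradient(s) ``F``.

    ``F`` has shape (..., 3, 3) with positive determinant.  ``strain``
    selects the Green-Lagrange measure E = (F^T F - I)/2 (default) or the
    unhalved left Cauchy-Green variant ``left_cg`` eps = F F^T - I.
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("det(F) <= 0: inverted configuration")
    lam = params.lame_lambda_s
    mu = params.mu_s
    eye = np.broadcast_to(np.eye(3), F.shape)
    if strain == "green":
        E = 0.5 * (np.swapaxes(F, -1, -2) @ F - eye)
    elif strain == "left_cg":
        E = np.swapaxes(F, -1, -2) @ F  # placeholder, replaced below
        E = F @ np.swapaxes(F, -1, -2) - eye
    else:
        raise ValueError(f"unknown strain measure {strain!r}")
    tr = np.trace(E, axis1=-2, axis2=-1)[..., None, None]
    S = lam * tr * np.asarray(np.eye(3)) + 2.0 * mu * E
    sigma = F @ S @ np.swapaxes(F, -1, -2) / J[..., None, None]
    return sigma


class SolidModel:
    """Axisymmetric P1 discretization of the SVK annulus.

    Works on the solid part of an :class:`AxisymMesh`.  Degrees of freedom
    are blocked as [u_r (all solid nodes), u_z (all solid nodes)] in local
    solid-node numbering.  Supplies the internal-force residual with its
    consistent tangent, the (lumped-free, consistent) mass matrix, and
    Dirichlet bookkeeping for the outer-fixed / deep-roller conditions.
    """

    def __init__(self, mesh: AxisymMesh, params: ModelParameters, strain: str = "green"):
        if mesh.tris_solid.size == 0:
            raise ValueError("mesh has no solid region")
        self.params = params
        self.strain = strain
        self.global_ids = mesh.solid_node_ids
        self.n = self.global_ids.shape[0]
        self.loc = -np.ones(mesh.n_nodes, dtype=np.int64)
        self.loc[self.global_ids] = np.arange(self.n)
        self.tris = self.loc[mesh.tris_solid]
        self.nodes = mesh.nodes[self.global_ids]
        self.geom = TriGeometry(self.nodes, self.tris)
        self.lam = lame_lambda(params.mu_s, params.nu)
        self.mu = params.mu_s

        # Dirichlet: clamp both components at r = R3, axial roller at z = 0
        fixed = self.loc[mesh.node_sets["brain_outer"]]
        roller = self.loc[mesh.node_sets["brain_deep_face"]]
        self.dirichlet = np.unique(np.concatenate([fixed, fixed + self.n, roller + self.n]))
        self.interface_local = self.loc[mesh.node_sets["pvs_brain_interface"]]

        # consistent mass blocks (same for r and z components)
        self._mass_blocks = self.geom.mass_blocks()
        self.M = assemble_coo(self._mass_blocks, self.tris, self.tris, (self.n, self.n))

        self._NQ = self.geom.NQ  # (3q, 3i)

    # -- kinematics at quadrature points -------------------------------------

    def _deformation(self, u: np.ndarray):
        """Meridional F (E, q, 2, 2) and hoop stretch (E, q) for dofs ``u``."""
        ur = u[: self.n][self.tris]  # (E, 3)
        uz = u[self.n:][self.tris]
        g = self.geom.grads  # (E, 3, 2)
        Fm = np.broadcast_to(np.eye(2), (self.tris.shape[0], 3, 2, 2)).copy()
        gradur = np.einsum("ei,eia->ea", ur, g)  # (E, 2)
        graduz = np.einsum("ei,eia->ea", uz, g)
        Fm[:, :, 0, 0] += gradur[:, None, 0]
        Fm[:, :, 0, 1] += gradur[:, None, 1]
        Fm[:, :, 1, 0] += graduz[:, None, 0]
        Fm[:, :, 1, 1] += graduz[:, None, 1]
        ur_q = np.einsum("qi,ei->eq", self._NQ, ur)
        Ft = 1.0 + ur_q / self.geom.r_q
        return Fm, Ft

    def internal_force(self, u: np.ndarray, tangent: bool = True):
        """Internal virtual work residual (2n,) and optionally its tangent."""
        E_, nq = self.tris.shape[0], 3
        g = self.geom.grads
        Fm, Ft = self._deformation(u)
        if np.any(Ft <= 0) or np.any(np.linalg.det(Fm) <= 0):
            raise FloatingPointError("solid element inverted (det F <= 0)")

        eye2 = np.eye(2)
        if self.strain == "green":
            Em = 0.5 * (np.einsum("eqka,eqkb->eqab", Fm, Fm) - eye2)
            Et = 0.5 * (Ft**2 - 1.0)
        else:  # unhalved left Cauchy-Green variant
            Em = np.einsum("eqak,eqbk->eqab", Fm, Fm) - eye2
            Et = Ft**2 - 1.0
        trE = np.einsum("eqaa->eq", Em) + Et
        Sm = self.lam * trE[..., None, None] * eye2 + 2.0 * self.mu * Em
        St = self.lam * trE + 2.0 * self.mu * Et

        wq = 2.0 * np.pi * self.geom.w_q * self.geom.r_q  # (E, q)
        if self.strain == "green":
            # S : dE = (F S) : dF with dE = sym(F^T dF)
            P = np.einsum("eqca,eqab->eqcb", Fm, Sm)
            hoop_fac = St * Ft
        else:
            # S : d(F F^T) = 2 (S F) : dF
            P = 2.0 * np.einsum("eqca,eqab->eqcb", Sm, Fm)
            hoop_fac = 2.0 * St * Ft
        Rloc = np.einsum("eq,eqcb,eib->eic", wq, P, g)
        Rloc[:, :, 0] += np.einsum("eq,qi->ei", wq * hoop_fac / self.geom.r_q, self._NQ)

        R = np.zeros(2 * self.n)
        np.add.at(R, self.tris, Rloc[:, :, 0])
        np.add.at(R, self.tris + self.n, Rloc[:, :, 1])
        if not tangent:
            return R, None

        # Consistent tangent of the Green-strain form; for the left_cg
        # variant this serves as an approximate Jacobian (Newton still
        # converges; only the converged residual defines the solution).
        # meridional: dEm[e,q,i,c,a,b] = 1/2 (Fm[c,a] g[i,b] + Fm[c,b] g[i,a])
        dEm = 0.5 * (
            np.einsum("eqca,eib->eqicab", Fm, g) + np.einsum("eqcb,eia->eqicab", Fm, g)
        )
        NoverR = self._NQ[None, :, :] / self.geom.r_q[:, :, None]  # (E,q,i)
        dEt = np.zeros((E_, nq, 3, 2))
        dEt[:, :, :, 0] = Ft[:, :, None] * NoverR
        if self.strain != "green":
            dEm = 2.0 * dEm
            dEt = 2.0 * dEt
        trdE = np.einsum("eqicaa->eqic", dEm) + dEt

        # material part
        Kmat = (
            self.lam * np.einsum("eq,eqic,eqjd->eicjd", wq, trdE, trdE)
            + 2.0 * self.mu * np.einsum("eq,eqicab,eqjdab->eicjd", wq, dEm, dEm)
            + 2.0 * self.mu * np.einsum("eq,eqic,eqjd->eicjd", wq, dEt, dEt)
        )
        # geometric part: (c==d) g_ia Sm_ab g_jb + (c==0)(d==0) St N_i N_j / R^2
        geo_m = np.einsum("eq,eia,eqab,ejb->eij", wq, g, Sm, g)
        geo_t = np.einsum("eq,qi,qj->eij", wq * St / self.geom.r_q**2, self._NQ, self._NQ)
        Kgeo = np.zeros_like(Kmat)
        for c in range(2):
            Kgeo[:, :, c, :, c] += geo_m
        Kgeo[:, :, 0, :, 0] += geo_t
        Kloc = Kmat + Kgeo

        dofs = np.concatenate([self.tris, self.tris + self.n], axis=1)  # (E, 6)
        blocks = Kloc.transpose(0, 2, 1, 4, 3).reshape(E_, 6, 6)
        K = assemble_coo(blocks, dofs, dofs, (2 * self.n, 2 * self.n))
        return R, K

    def strain_energy(self, u: np.ndarray) -> float:
        """Total SVK strain energy int [lam/2 tr(E)^2 + mu E:E] dV, J."""
        Fm, Ft = self._deformation(u)
        eye2 = np.eye(2)
        Em = 0.5 * (np.einsum("eqka,eqkb->eqab", Fm, Fm) - eye2)
        Et = 0.5 * (Ft**2 - 1.0)
        trE = np.einsum("eqaa->eq", Em) + Et
        EE = np.einsum("eqab,eqab->eq", Em, Em) + Et**2
        wq = 2.0 * np.pi * self.geom.w_q * self.geom.r_q
        return float(np.sum(wq * (0.5 * self.lam * trE**2 + self.mu * EE)))

    def kinetic_energy(self, v: np.ndarray, rho: float) -> float:
        """Kinetic energy 1/2 rho v^T M v of the tissue, J."""
        return 0.5 * rho * (v[: self.n] @ (self.M @ v[: self.n])
                            + v[self.n:] @ (self.M @ v[self.n:]))

    # -- loading and solving -------------------------------------------------

    def interface_pressure_load(self, pressure: np.ndarray) -> np.ndarray:
        """Consistent nodal load of a pressure p(z) acting outward on the
        inner (interface) face.  ``pressure`` gives Pa at the interface
        nodes ordered by increasing z.  Returns a (2n,) load vector."""
        ids = self.interface_local
        z = self.nodes[ids, 1]
        R2 = self.nodes[ids, 0]
        f = np.zeros(2 * self.n)
        for k in range(len(ids) - 1):
            L = z[k + 1] - z[k]
            p1, p2 = pressure[k], pressure[k + 1]
            r1, r2 = R2[k], R2[k + 1]
            # int N_i p(z) 2 pi r dz on the segment, linear p and r
            f[ids[k]] += 2.0 * np.pi * L * (r1 * (3 * p1 + p2) + r2 * (p1 + p2)) / 12.0
            f[ids[k + 1]] += 2.0 * np.pi * L * (r2 * (p1 + 3 * p2) + r1 * (p1 + p2)) / 12.0
        return f

    def apply_dirichlet(self, K: sp.spmatrix, R: np.ndarray):
        K = K.tolil()
        for d in self.dirichlet:
            K.rows[d] = [d]
            K.data[d] = [1.0]
        R = R.copy()
        R[self.dirichlet] = 0.0
        return K.tocsr(), R

    def static_solve(self, load: np.ndarray, tol: float = 1e-10, maxiter: int = 20,
                     extra_roller_pial: bool = False) -> np.ndarray:
        """Newton solve of the static problem K(u) = load.

        ``extra_roller_pial`` additionally constrains axial displacement on
        the pial face (plane-strain-like conditions, used when comparing
        against the thick-cylinder closed form).
        """
        dirichlet = self.dirichlet
        if extra_roller_pial:
            # pial face nodes are those with z = max z
            zmax = self.nodes[:, 1].max()
            pial = np.where(np.isclose(self.nodes[:, 1], zmax))[0]
            dirichlet = np.unique(np.concatenate([dirichlet, pial + self.n]))
        u = np.zeros(2 * self.n)
        scale = max(np.linalg.norm(load), 1e-30)
        for _ in range(maxiter):
            R, K = self.internal_force(u)
            res = R - load
            res[dirichlet] = 0.0
            if np.linalg.norm(res) < tol * scale:
                break
            K = K.tolil()
            for d in dirichlet:
                K.rows[d] = [d]
                K.data[d] = [1.0]
            du = spla.spsolve(K.tocsr(), -res)
            u = u + du
        return u


def lame_annulus_displacement(p: float, a: float, b: float, mu: float, lam: float) -> float:
    """Radial displacement at r = a of a plane-strain thick cylinder with
    internal pressure ``p``, outer wall fixed (u(b) = 0).  Closed form used
    as the small-load oracle for the axisymmetric SVK solver."""
    A = -p / (2.0 * (lam + mu) + 2.0 * mu * b**2 / a**2)
    return A * (a - b**2 / a)


def static_tissue_estimate(
    pressure_profile: np.ndarray,
    params: ModelParameters,
    mesh: AxisymMesh | None = None,
    nz: int | None = None,
    nr_brain: int = 14,
) -> float:
    """Peak radial tissue displacement (m) from a static SVK solve loaded
    with the PVS pressure profile ``pressure_profile`` (Pa at equally
    spaced axial stations from z = 0 to z = La) applied as outward normal
    traction on the inner face of the brain annulus."""
    pressure_profile = np.asarray(pressure_profile, dtype=float)
    if mesh is None:
        nz = nz or (len(pressure_profile) - 1)
        mesh = build_mesh(params, nr_pvs=4, nz=nz, nr_brain=nr_brain)
    model = SolidModel(mesh, params)
    z_nodes = model.nodes[model.interface_local, 1]
    z_in = np.linspace(0.0, params.La, len(pressure_profile))
    p_nodes = np.interp(z_nodes, z_in, pressure_profile)
    load = model.interface_pressure_load(p_nodes)
    u = model.static_solve(load)
    return float(np.max(np.abs(u[: model.n])))
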