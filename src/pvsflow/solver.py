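"""Axisymmetric Darcy-Brinkman / Navier-Stokes flow in the deforming PVS,
optionally fully coupled to the Saint-Venant-Kirchhoff brain annulus.

Formulation
-----------
The fluid momentum balance in the porous PVS is

    rho_f [dv/dt + ((v - w) . grad) v] + (mu_f zeta / k_s) v
        = div sigma_f,            sigma_f = -p I + mu_f (grad v + grad v^T),

with div v = 0, written in arbitrary Lagrangian-Eulerian (ALE) form on a
mesh that follows the moving arteriolar wall and brain-PVS interface
(``w`` is the mesh velocity).  Infinite permeability drops the drag term
and recovers Navier-Stokes.  Equal-order P1/P1 elements are stabilized
with a residual-based pressure-Poisson (PSPG) term whose coefficient
adapts between the viscous- and drag-dominated limits; the drag and
inertia parts of the momentum residual are kept in the stabilization so
that the scheme stays mass-consistent in the Darcy regime.

The two axial ends of the PVS carry Robin (resistance) conditions: the
applied traction is -R_out * q(t) * n with q the instantaneous signed
volumetric outflow through that end, R_out = r_sas * R_PVS at the pial end
and r_par * R_PVS at the parenchymal end.  The ``free`` variant applies
zero traction instead.

In coupled (FSI) mode the fluid velocity on the interface equals the tissue
velocity, the mesh follows the tissue displacement (harmonic extension into
the PVS), and the traction balance is enforced monolithically: interface
fluid test functions are identified with solid test functions through the
kinematic constraint, so a single Newton loop advances fluid, pressure and
tissue unknowns together.  Time stepping is BDF2 with a BDF1 start; the
domain geometry within each step is converged by a small fixed-point loop
(predict interface position, solve, re-extend the mesh).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from pvsflow.fem import TriGeometry, assemble_coo, edge_normal_weights
from pvsflow.mesh import AxisymMesh, build_mesh
from pvsflow.parameters import ModelParameters, outlet_reference_resistance, pvs_reference_resistance
from pvsflow.solid import SolidModel
from pvsflow.wall_motion import WallMotion

__all__ = ["FlowRecord", "run_rigid", "run_coupled", "harmonic_mesh_motion", "MeshMotion", "Simulation"]


# ---------------------------------------------------------------------------
# mesh motion


class MeshMotion:
    """Harmonic extension of boundary motion into the PVS mesh.

    Solves a component-wise Laplace problem on the reference fluid mesh with
    Dirichlet data on the arteriolar wall and the brain-PVS interface; the
    axial ends slide (zero axial mesh motion, free radial).  The operator is
    factorized once and reused.
    """

    def __init__(self, mesh: AxisymMesh):
        self.mesh = mesh
        ids = mesh.fluid_node_ids
        self.nf = ids.shape[0]
        self.wall = mesh.node_sets["arteriole_wall"]
        self.interface = mesh.node_sets["pvs_brain_interface"]
        ends = np.concatenate([mesh.node_sets["parenchymal_end"], mesh.node_sets["pial_end"]])
        geom = TriGeometry(mesh.nodes[:self.nf], mesh.tris_fluid)
        K = assemble_coo(geom.stiffness_blocks(axisym=False), mesh.tris_fluid,
                         mesh.tris_fluid, (self.nf, self.nf))
        self.dir_r = np.unique(np.concatenate([self.wall, self.interface]))
        self.dir_z = np.unique(np.concatenate([self.wall, self.interface, ends]))
        self.lu = {}
        for tag, dirich in (("r", self.dir_r), ("z", self.dir_z)):
            A = K.tolil()
            for d in dirich:
                A.rows[d] = [d]
                A.data[d] = [1.0]
            self.lu[tag] = spla.splu(A.tocsc())

    def extend(self, wall_disp: np.ndarray, interface_disp: np.ndarray) -> np.ndarray:
        """Mesh displacement (nf, 2) from radial wall data and (n_if, 2)
        interface data."""
        um = np.zeros((self.nf, 2))
        rhs = np.zeros(self.nf)
        rhs[self.wall] = wall_disp
        rhs[self.interface] = interface_disp[:, 0]
        um[:, 0] = self.lu["r"].solve(rhs)
        rhs = np.zeros(self.nf)
        rhs[self.interface] = interface_disp[:, 1]
        um[:, 1] = self.lu["z"].solve(rhs)
        return um


def harmonic_mesh_motion(mesh: AxisymMesh, wall_disp: np.ndarray,
                         interface_disp: np.ndarray) -> np.ndarray:
    """One-off harmonic mesh-displacement solve (see :class:`MeshMotion`).

    ``wall_disp``: radial displacement at the arteriole-wall nodes;
    ``interface_disp``: radial (n,) or full (n, 2) displacement at the
    interface nodes.  Returns the (n_fluid_nodes, 2) displacement field.
    """
    interface_disp = np.asarray(interface_disp, dtype=float)
    if interface_disp.ndim == 1:
        interface_disp = np.column_stack([interface_disp, np.zeros_like(interface_disp)])
    return MeshMotion(mesh).extend(np.asarray(wall_disp, dtype=float), interface_disp)


# ---------------------------------------------------------------------------
# record


@dataclass
class FlowRecord:
    """Time series and field snapshots produced by a simulation run.

    Fluxes are signed with positive = out of the PVS.  ``q_pial`` is the
    flow rate through the pial end z = La (the q_f0 of the Peclet
    definitions) and ``q_f50`` the flow rate through the cross-section
    50 um below the brain surface.  ``p_interface`` / ``ur_interface`` hold
    per-step profiles along the brain-PVS interface ordered by z, and
    ``mass_residual`` the per-step defect dV/dt + q_pial + q_deep, which
    vanishes for an exactly mass-conserving scheme.
    """

    params: ModelParameters
    times: np.ndarray
    q_pial: np.ndarray
    q_deep: np.ndarray
    q_f50: np.ndarray
    volume: np.ndarray
    mean_vz: np.ndarray
    peak_speed: float
    p_interface: np.ndarray
    ur_interface: np.ndarray
    z_interface: np.ndarray
    wall_disp: np.ndarray
    mode: str = "rigid"
    snapshots: dict = field(default_factory=dict)
    mass_residual: np.ndarray | None = None
    energy_elastic: np.ndarray | None = None
    energy_kinetic: np.ndarray | None = None

    @property
    def q_f0(self) -> np.ndarray:
        return self.q_pial

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def peak_pressure_profile(self) -> np.ndarray:
        """Interface pressure profile at the instant of largest |p|."""
        i = int(np.argmax(np.max(np.abs(self.p_interface), axis=1)))
        return self.p_interface[i]

    def cumulative_outflow(self, end: str = "pial") -> np.ndarray:
        """Time-integrated net outflow (m^3) through one end (trapezoid,
        from rest at t = 0)."""
        q = {"pial": self.q_pial, "deep": self.q_deep}[end]
        qfull = np.concatenate([[0.0], q])
        tfull = np.concatenate([[0.0], self.times])
        return np.cumsum(np.concatenate(
            [[0.0], 0.5 * (qfull[1:] + qfull[:-1]) * np.diff(tfull)]))[1:]


# ---------------------------------------------------------------------------
# fluid assembly on a configuration


class _FluidAssembler:
    """Assembles the stabilized P1/P1 fluid operators on a given (possibly
    deformed) configuration of the PVS triangulation."""

    def __init__(self, mesh: AxisymMesh, params: ModelParameters):
        self.mesh = mesh
        self.params = params
        self.nf = mesh.fluid_node_ids.shape[0]
        self.tris = mesh.tris_fluid
        self.R_pvs = pvs_reference_resistance(params)
        self.drag = 0.0 if params.navier_stokes else params.mu_f * params.zeta / params.k_s

    def operators(self, coords: np.ndarray, c0_dt: float, conv_vel: np.ndarray | None):
        p = self.params
        geom = TriGeometry(coords, self.tris)
        nf, tris = self.nf, self.tris
        M = assemble_coo(geom.mass_blocks(), tris, tris, (nf, nf))

        scale = 2.0 * np.pi * geom.area * geom.r_c
        g = geom.grads
        mu = p.mu_f
        k_rr = 2.0 * mu * (
            np.einsum("e,ei,ej->eij", scale, g[:, :, 0], g[:, :, 0])
            + 0.5 * np.einsum("e,ei,ej->eij", scale, g[:, :, 1], g[:, :, 1])
        ) + 2.0 * mu * geom.inv_r_mass_blocks()
        k_zz = 2.0 * mu * (
            np.einsum("e,ei,ej->eij", scale, g[:, :, 1], g[:, :, 1])
            + 0.5 * np.einsum("e,ei,ej->eij", scale, g[:, :, 0], g[:, :, 0])
        )
        k_rz = mu * np.einsum("e,ei,ej->eij", scale, g[:, :, 1], g[:, :, 0])
        k_zr = mu * np.einsum("e,ei,ej->eij", scale, g[:, :, 0], g[:, :, 1])

        Krr = assemble_coo(k_rr, tris, tris, (nf, nf))
        Kzz = assemble_coo(k_zz, tris, tris, (nf, nf))
        Krz = assemble_coo(k_rz, tris, tris, (nf, nf))
        Kzr = assemble_coo(k_zr, tris, tris, (nf, nf))

        # divergence D[p_i, (vr|vz)_j]; the hoop term int N_i N_j / r 2 pi r
        int_NiNj = np.einsum("eq,qi,qj->eij", geom.w_q, geom.NQ, geom.NQ)
        int_Ni_r = np.einsum("eq,qi->ei", geom.w_q * geom.r_q, geom.NQ)
        d_r = 2.0 * np.pi * (np.einsum("ei,ej->eij", int_Ni_r, g[:, :, 0]) + int_NiNj)
        d_z = 2.0 * np.pi * np.einsum("ei,ej->eij", int_Ni_r, g[:, :, 1])
        Dr = assemble_coo(d_r, tris, tris, (nf, nf))
        Dz = assemble_coo(d_z, tris, tris, (nf, nf))

        # Oseen convection with the lagged ALE advection velocity
        if conv_vel is not None:
            a_c = conv_vel[tris].mean(axis=1)
            adg = np.einsum("ea,eja->ej", a_c, g)
            conv = p.rho_f * np.einsum("ei,ej->eij", 2.0 * np.pi * int_Ni_r, adg)
            Cv = assemble_coo(conv, tris, tris, (nf, nf))
        else:
            Cv = sp.csr_matrix((nf, nf))

        # PSPG coefficient; sigma_eff collects the zeroth-order momentum terms
        h2 = 4.0 * geom.area / math.sqrt(3.0)
        sigma_eff = self.drag + p.rho_f * c0_dt
        tau = 1.0 / (sigma_eff + 12.0 * mu / h2)
        Sp = assemble_coo(geom.stiffness_blocks(weight=tau), tris, tris, (nf, nf))
        # unit-strength residual term: Gunit[q_i, v_aj] = tau int N_j d_a N_i 2 pi r
        g_r = 2.0 * np.pi * tau[:, None, None] * np.einsum("ei,ej->eij", g[:, :, 0], int_Ni_r)
        g_z = 2.0 * np.pi * tau[:, None, None] * np.einsum("ei,ej->eij", g[:, :, 1], int_Ni_r)
        Gunit = sp.hstack([
            assemble_coo(g_r, tris, tris, (nf, nf)),
            assemble_coo(g_z, tris, tris, (nf, nf)),
        ]).tocsr()

        Avv = p.rho_f * c0_dt * M + self.drag * M
        A = sp.bmat([[Avv + Krr + Cv, Krz], [Kzr, Avv + Kzz + Cv]]).tocsr()
        D = sp.hstack([Dr, Dz]).tocsr()
        B = (-D.T).tocsr()
        L = np.zeros(nf)
        np.add.at(L, tris.ravel(), geom.load_vector_blocks().ravel())
        return {
            "A": A, "B": B, "D": D, "Gunit": Gunit, "Sp": Sp, "M": M,
            "geom": geom, "L": L, "sigma_eff": sigma_eff,
        }


# ---------------------------------------------------------------------------
# the time-dependent simulation


class Simulation:
    """Shared machinery for rigid and coupled runs; public entry points are
    :func:`run_rigid` and :func:`run_coupled`."""

    def __init__(
        self,
        params: ModelParameters,
        motion: WallMotion,
        mode: str = "fsi",
        outlets: str = "robin",
        nr_pvs: int = 10,
        nz: int = 48,
        nr_brain: int = 14,
        dt: float | None = None,
        duration: float | None = None,
        store_every: int = 0,
        newton_tol: float = 1e-9,
        geometry_tol: float = 1e-13,
        max_geometry_iters: int = 3,
        outlet_reference: str = "darcy",
    ):
        if mode not in {"rigid", "fsi"}:
            raise ValueError(f"unknown mode {mode!r}")
        if outlets not in {"robin", "free"}:
            raise ValueError(f"unknown outlet treatment {outlets!r}")
        self.params = params
        self.motion = motion
        self.mode = mode
        self.outlets = outlets
        self.mesh = build_mesh(params, nr_pvs=nr_pvs, nz=nz, nr_brain=nr_brain,
                               include_brain=(mode == "fsi"))
        self.dt = dt if dt is not None else (1e-4 if motion.kind == "heartbeat" else 1e-2)
        if duration is None:
            duration = motion.duration
        self.n_steps = max(int(round(duration / self.dt)), 1)
        self.store_every = store_every
        self.newton_tol = newton_tol
        self.geometry_tol = geometry_tol
        self.max_geometry_iters = max_geometry_iters

        m = self.mesh
        self.nf = m.fluid_node_ids.shape[0]
        self.fluid = _FluidAssembler(m, params)
        self.mesh_motion = MeshMotion(m)
        self.ref_coords = m.nodes[: self.nf].copy()

        # The Robin outlets represent anatomy outside the PVS; by default
        # their values stay anchored to the physiological Darcy resistance
        # even when the PVS interior is idealized as an open channel
        # ("darcy").  "poiseuille" re-normalizes them to the open-channel
        # resistance instead (the pure free-channel idealization).
        if outlet_reference == "darcy":
            R_ref = outlet_reference_resistance(params)
        elif outlet_reference == "poiseuille":
            R_ref = pvs_reference_resistance(params)
        else:
            raise ValueError(f"unknown outlet_reference {outlet_reference!r}")
        self.R_out = {"pial": params.r_sas * R_ref, "deep": params.r_par * R_ref}
        self.end_edges = {
            "pial": m.edge_sets["pial_end"],
            "deep": m.edge_sets["parenchymal_end"],
        }
        self.end_nz = {"pial": +1.0, "deep": -1.0}
        self.sec50_edges = m.fluid_cross_section_edges(params.La - 50e-6)

        self.wall = m.node_sets["arteriole_wall"]
        self.interface = m.node_sets["pvs_brain_interface"]
        self.z_wall = m.nodes[self.wall, 1].copy()
        self.z_interface = m.nodes[self.interface, 1].copy()

        self.solid = SolidModel(m, params) if mode == "fsi" else None
        self._build_dof_maps()

    # -- dof bookkeeping -----------------------------------------------------

    def _build_dof_maps(self):
        nf = self.nf
        dirichlet_v = set(self.wall.tolist()) | set((self.wall + nf).tolist())
        if self.mode == "fsi":
            tied_v = np.concatenate([self.interface, self.interface + nf])
        else:
            tied_v = np.empty(0, dtype=np.int64)
            dirichlet_v |= set(self.interface.tolist()) | set((self.interface + nf).tolist())
        self.tied_v = tied_v
        free_mask = np.ones(2 * nf, dtype=bool)
        free_mask[sorted(dirichlet_v)] = False
        free_mask[tied_v] = False
        self.free_v = np.where(free_mask)[0]
        self.n_free_v = self.free_v.shape[0]

        if self.mode == "fsi":
            s = self.solid
            free_s = np.ones(2 * s.n, dtype=bool)
            free_s[s.dirichlet] = False
            self.free_s = np.where(free_s)[0]
            self.n_free_s = self.free_s.shape[0]
            if_loc = s.interface_local
            self.tied_solid_dofs = np.concatenate([if_loc, if_loc + s.n])
        else:
            self.free_s = np.empty(0, dtype=np.int64)
            self.n_free_s = 0
        self.n_reduced = self.n_free_v + nf + self.n_free_s

    def _transformation(self, c0_dt: float) -> tuple[sp.csr_matrix, sp.csr_matrix]:
        """Raw-to-reduced dof maps; raw = [v (2nf); p (nf); u (2ns)].

        Returns (T_trial, T_test).  Both tie the interface fluid dofs to the
        interface solid dofs, but with different weights: the trial map
        carries the BDF factor c0/dt (the interface fluid *velocity* equals
        the discrete time derivative of the solid displacement), while the
        test map uses weight 1 so that interface fluid and solid residuals
        are summed with the same test function -- that sum enforces the
        traction balance sigma_f . n = sigma_s . n.
        """
        nf = self.nf
        n_solid_raw = 2 * self.solid.n if self.mode == "fsi" else 0
        n_raw = 3 * nf + n_solid_raw
        rows = list(self.free_v) + list(2 * nf + np.arange(nf))
        cols = list(range(self.n_free_v + nf))
        vals = [1.0] * len(rows)
        tie_rows, tie_cols = [], []
        if self.mode == "fsi":
            offset = self.n_free_v + nf
            solid_col = -np.ones(n_solid_raw, dtype=np.int64)
            solid_col[self.free_s] = np.arange(self.n_free_s)
            rows += list(3 * nf + self.free_s)
            cols += list(offset + np.arange(self.n_free_s))
            vals += [1.0] * self.n_free_s
            for vd, sd in zip(self.tied_v, self.tied_solid_dofs):
                c = solid_col[sd]
                if c >= 0:
                    tie_rows.append(int(vd))
                    tie_cols.append(int(offset + c))
        T_trial = sp.coo_matrix(
            (vals + [c0_dt] * len(tie_rows), (rows + tie_rows, cols + tie_cols)),
            shape=(n_raw, self.n_reduced)).tocsr()
        T_test = sp.coo_matrix(
            (vals + [1.0] * len(tie_rows), (rows + tie_rows, cols + tie_cols)),
            shape=(n_raw, self.n_reduced)).tocsr()
        return T_trial, T_test

    # -- helpers -------------------------------------------------------------

    def _outflow_vector(self, coords: np.ndarray, which: str) -> np.ndarray:
        ids, w = edge_normal_weights(coords, self.end_edges[which], self.end_nz[which])
        b = np.zeros(2 * self.nf)
        b[ids + self.nf] = w
        return b

    def _section_flux(self, coords: np.ndarray, vz: np.ndarray, edges: np.ndarray) -> float:
        ids, w = edge_normal_weights(coords, edges, +1.0)
        return float(w @ vz[ids])

    # -- main loop -----------------------------------------------------------

    def run(self) -> FlowRecord:
        nf = self.nf
        params = self.params
        dt = self.dt
        v1 = np.zeros(2 * nf)
        v2 = np.zeros(2 * nf)
        v_free = np.zeros(2 * nf)  # free-dof working vector (raw indexing)
        pfield = np.zeros(nf)
        if self.mode == "fsi":
            ns2 = 2 * self.solid.n
            u = np.zeros(ns2)
            u1 = np.zeros(ns2)
            u2 = np.zeros(ns2)
            vs1 = np.zeros(ns2)
            vs2 = np.zeros(ns2)

        nt = self.n_steps
        times = np.arange(1, nt + 1) * dt
        rec = {k: np.zeros(nt) for k in ["q_pial", "q_deep", "q_f50", "volume", "mean_vz",
                                         "mass", "e_el", "e_kin"]}
        p_if = np.zeros((nt, len(self.interface)))
        ur_if = np.zeros((nt, len(self.interface)))
        wall_tr = np.zeros(nt)
        peak_speed = 0.0
        snaps = {"t": [], "coords": [], "vr": [], "vz": [], "p": []} if self.store_every else {}
        vol_prev = self.params.pvs_volume
        q_net_prev = 0.0
        # histories start from the t = 0 configuration; for the travelling
        # heartbeat wave the initial wall displacement is small but nonzero
        wall_d1 = np.asarray(self.motion.displacement(self.z_wall, 0.0), dtype=float)
        wall_d2 = wall_d1.copy()
        um1 = self.mesh_motion.extend(wall_d1, np.zeros((len(self.interface), 2)))
        um2 = um1.copy()
        vol_prev = TriGeometry(self.ref_coords + um1, self.mesh.tris_fluid).volume()

        for n in range(1, nt + 1):
            t = n * dt
            if n == 1:
                c0 = 1.0
                hv = v1.copy()
            else:
                c0 = 1.5
                hv = 2.0 * v1 - 0.5 * v2
            c0_dt = c0 / dt

            if self.mode == "fsi":
                hu = (2.0 * u1 - 0.5 * u2) if n > 1 else u1.copy()
                hvs = (2.0 * vs1 - 0.5 * vs2) if n > 1 else vs1.copy()
                u = (2.0 * u1 - u2) if n > 1 else u1.copy()

            wall_d = self.motion.displacement(self.z_wall, t)
            # discretely consistent no-slip data: the same BDF derivative of
            # the wall displacement that moves the mesh (keeps the boundary
            # kinematics and the domain-volume change in exact agreement)
            if n == 1:
                wall_v = (c0 * wall_d - wall_d1) / dt
            else:
                wall_v = (c0 * wall_d - (2.0 * wall_d1 - 0.5 * wall_d2)) / dt
            wall_tr[n - 1] = float(np.max(np.abs(wall_d)))

            T_trial, T_test = self._transformation(c0_dt)

            for g_it in range(self.max_geometry_iters):
                if self.mode == "fsi":
                    iface_d = np.column_stack([
                        u[self.solid.interface_local],
                        u[self.solid.interface_local + self.solid.n],
                    ])
                else:
                    iface_d = np.zeros((len(self.interface), 2))
                um = self.mesh_motion.extend(wall_d, iface_d)
                coords = self.ref_coords + um
                hum = (2.0 * um1 - 0.5 * um2) if n > 1 else um1
                w_mesh = (c0 * um - hum) / dt

                conv = np.column_stack([v1[:nf], v1[nf:]]) - w_mesh
                ops = self.fluid.operators(coords, c0_dt, conv)
                A = ops["A"]
                if self.outlets == "robin":
                    for which in ("pial", "deep"):
                        b = self._outflow_vector(coords, which)
                        idx = np.nonzero(b)[0]
                        bb = sp.coo_matrix(
                            (np.outer(b[idx], b[idx]).ravel(),
                             (np.repeat(idx, idx.size), np.tile(idx, idx.size))),
                            shape=A.shape)
                        A = A + self.R_out[which] * bb.tocsr()

                rho = params.rho_f
                rhs_v = (rho / dt) * np.concatenate([ops["M"] @ hv[:nf], ops["M"] @ hv[nf:]])
                rhs_p = (rho / dt) * (ops["Gunit"] @ hv)
                G = ops["sigma_eff"] * ops["Gunit"]

                g_raw_v = np.zeros(2 * nf)
                g_raw_v[self.wall] = wall_v
                if self.mode == "fsi":
                    g_raw_v[self.tied_v] = -hu[self.tied_solid_dofs] / dt

                ref_norm = None
                res_prev = None
                for it in range(12):
                    v_raw = np.zeros(2 * nf)
                    v_raw[self.free_v] = v_free[self.free_v]
                    v_raw += g_raw_v
                    if self.mode == "fsi":
                        v_raw[self.tied_v] += c0_dt * u[self.tied_solid_dofs]

                    R_v = A @ v_raw + ops["B"] @ pfield - rhs_v
                    R_p = ops["D"] @ v_raw + ops["Sp"] @ pfield + G @ v_raw - rhs_p
                    if self.mode == "fsi":
                        s = self.solid
                        vs = (c0 * u - hu) / dt
                        acc = (c0 * vs - hvs) / dt
                        Rs, Ks = s.internal_force(u)
                        Macc = params.rho_s * np.concatenate(
                            [s.M @ acc[: s.n], s.M @ acc[s.n:]])
                        raw_res = np.concatenate([R_v, R_p, Rs + Macc])
                    else:
                        raw_res = np.concatenate([R_v, R_p])

                    red_res = T_test.T @ raw_res
                    res_norm = float(np.linalg.norm(red_res))
                    if ref_norm is None:
                        ref_norm = max(res_norm, 1e-300)
                    elif res_norm < self.newton_tol * ref_norm:
                        break
                    elif res_prev is not None and res_norm > 0.5 * res_prev:
                        # stalled at the round-off floor of a (nearly) linear
                        # step: accept
                        break
                    res_prev = res_norm

                    if self.mode == "fsi":
                        mass_fac = params.rho_s * (c0 * c0) / (dt * dt)
                        Ksys = Ks + mass_fac * sp.block_diag([s.M, s.M]).tocsr()
                        J_raw = sp.bmat([
                            [A, ops["B"], None],
                            [ops["D"] + G, ops["Sp"], None],
                            [None, None, Ksys],
                        ]).tocsr()
                    else:
                        J_raw = sp.bmat([[A, ops["B"]], [ops["D"] + G, ops["Sp"]]]).tocsr()

                    J_red = (T_test.T @ J_raw @ T_trial).tocsc()
                    dx = spla.spsolve(J_red, -red_res)
                    if not np.all(np.isfinite(dx)):
                        raise RuntimeError(f"singular coupled system at step {n} (t={t:.4g}s)")
                    v_free[self.free_v] += dx[: self.n_free_v]
                    pfield += dx[self.n_free_v: self.n_free_v + nf]
                    if self.mode == "fsi":
                        du = np.zeros(2 * s.n)
                        du[self.free_s] = dx[self.n_free_v + nf:]
                        u = u + du
                else:
                    if res_norm > 1e-6 * ref_norm:
                        raise RuntimeError(
                            f"Newton failed at step {n} (t={t:.4g}s), residual {res_norm:.3e}")

                if self.mode != "fsi":
                    break
                new_iface = np.column_stack([
                    u[self.solid.interface_local],
                    u[self.solid.interface_local + self.solid.n],
                ])
                if np.max(np.abs(new_iface - iface_d)) < max(
                        self.geometry_tol, 1e-6 * np.max(np.abs(new_iface) + 1e-30)):
                    break

            v_raw = np.zeros(2 * nf)
            v_raw[self.free_v] = v_free[self.free_v]
            v_raw += g_raw_v
            if self.mode == "fsi":
                v_raw[self.tied_v] += c0_dt * u[self.tied_solid_dofs]

            vr, vz = v_raw[:nf], v_raw[nf:]
            geom = ops["geom"]
            vol = geom.volume()
            rec["volume"][n - 1] = vol
            rec["q_pial"][n - 1] = float(self._outflow_vector(coords, "pial") @ v_raw)
            rec["q_deep"][n - 1] = float(self._outflow_vector(coords, "deep") @ v_raw)
            rec["q_f50"][n - 1] = self._section_flux(coords, vz, self.sec50_edges)
            rec["mean_vz"][n - 1] = float(ops["L"] @ vz) / vol
            # trapezoid-consistent mass defect: (V_n - V_{n-1})/dt vs the
            # midpoint net outflow (both O(dt^2) accurate)
            q_net = rec["q_pial"][n - 1] + rec["q_deep"][n - 1]
            rec["mass"][n - 1] = (vol - vol_prev) / dt + 0.5 * (q_net + q_net_prev)
            vol_prev = vol
            q_net_prev = q_net
            p_if[n - 1] = pfield[self.interface]
            if self.mode == "fsi":
                ur_if[n - 1] = u[self.solid.interface_local]
                vs_now = (c0 * u - hu) / dt
                rec["e_el"][n - 1] = self.solid.strain_energy(u)
                rec["e_kin"][n - 1] = self.solid.kinetic_energy(vs_now, params.rho_s)
            peak_speed = max(peak_speed, float(np.max(np.hypot(vr, vz))))

            if self.store_every and (n % self.store_every == 0 or n == nt):
                snaps["t"].append(t)
                snaps["coords"].append(coords.copy())
                snaps["vr"].append(vr.copy())
                snaps["vz"].append(vz.copy())
                snaps["p"].append(pfield.copy())

            v2, v1 = v1, v_raw.copy()
            um2, um1 = um1, um.copy()
            wall_d2, wall_d1 = wall_d1, np.asarray(wall_d, dtype=float).copy()
            if self.mode == "fsi":
                vs = (c0 * u - hu) / dt
                u2, u1 = u1, u.copy()
                vs2, vs1 = vs1, vs.copy()

        return FlowRecord(
            params=params,
            times=times,
            q_pial=rec["q_pial"],
            q_deep=rec["q_deep"],
            q_f50=rec["q_f50"],
            volume=rec["volume"],
            mean_vz=rec["mean_vz"],
            peak_speed=peak_speed,
            p_interface=p_if,
            ur_interface=ur_if,
            z_interface=self.z_interface,
            wall_disp=wall_tr,
            mode=self.mode,
            snapshots=snaps,
            mass_residual=rec["mass"],
            energy_elastic=rec["e_el"],
            energy_kinetic=rec["e_kin"],
        )


def steady_pressure_driven_flow(params: ModelParameters, dp: float,
                                nr_pvs: int = 24, nz: int = 24):
    """Steady axial flow through the rigid annulus under a pressure drop.

    Solves the stationary Darcy-Brinkman (or Stokes) problem with no-slip
    walls, a normal traction ``dp`` applied at the parenchymal end and zero
    traction at the pial end.  Returns (r coordinates across the gap at
    mid-channel, axial velocity profile v_z(r), volumetric flow rate).
    Used to validate the discretization against the one-dimensional
    Brinkman two-point boundary-value problem.
    """
    motion = WallMotion(kind="sinusoid", amplitude=0.0, La=params.La, f=1.0,
                        duration=1.0)
    sim = Simulation(params, motion, mode="rigid", outlets="free",
                     nr_pvs=nr_pvs, nz=nz, dt=1.0, duration=1.0)
    nf = sim.nf
    coords = sim.ref_coords
    ops = sim.fluid.operators(coords, 0.0, None)
    A = ops["A"]
    rhs_v = np.zeros(2 * nf)
    # traction dp at the deep end (outward normal -z): adds dp * int phi.n
    ids, w = edge_normal_weights(coords, sim.end_edges["deep"], -1.0)
    rhs_v[ids + nf] = -dp * w  # -(-p n) with p = dp pushes flow toward +z
    T_trial, T_test = sim._transformation(1.0)
    Gm = ops["sigma_eff"] * ops["Gunit"]
    J = sp.bmat([[A, ops["B"]], [ops["D"] + Gm, ops["Sp"]]]).tocsr()
    J_red = (T_test.T @ J @ T_trial).tocsc()
    rhs = T_test.T @ np.concatenate([rhs_v, np.zeros(nf)])
    x = spla.spsolve(J_red, rhs)
    v_raw = np.zeros(2 * nf)
    v_raw[sim.free_v] = x[: sim.n_free_v]
    vz = v_raw[nf:]
    # mid-channel radial profile
    j = nz // 2
    line = sim.mesh._fluid_line(j)
    r = coords[line, 0]
    ids_q, w_q = edge_normal_weights(coords, sim.mesh.fluid_cross_section_edges(params.La / 2), 1.0)
    q = float(w_q @ vz[ids_q])
    return r, vz[line], q


def run_rigid(params: ModelParameters, motion: WallMotion, outlets: str = "robin",
              **options) -> FlowRecord:
    """Time-march the rigid-outer-wall model (interface fixed, no solid).

    ``outlets``: "robin" (default lumped resistances) or "free" (zero
    traction).  Resolution and time options forwarded to
    :class:`Simulation`.
    """
    return Simulation(params, motion, mode="rigid", outlets=outlets, **options).run()


def run_coupled(params: ModelParameters, motion: WallMotion, **options) -> FlowRecord:
    """Time-march the fully coupled fluid-structure interaction model."""
    return Simulation(params, motion, mode="fsi", **options).run()
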