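"""Structured axisymmetric meshes for the PVS annulus and brain-tissue section.

The meridional (r, z) domain is a pair of rectangles sharing the line
r = R2 = R1 + wd: the fluid-filled PVS (R1 <= r <= R2) and the brain-tissue
annulus (R2 <= r <= R3), both spanning 0 <= z <= La, with z = 0 the
parenchymal (deep) end and z = La the pial end.  Each rectangle is meshed by
a tensor-product grid split into triangles.  Radial points in the PVS are
clustered toward both walls (the Brinkman boundary layer sqrt(k_s/zeta) is
a fraction of a micrometre); brain-tissue points grow geometrically away
from the interface where the traction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pvsflow.parameters import ModelParameters

__all__ = ["AxisymMesh", "build_mesh", "graded_points"]


def graded_points(a: float, b: float, n: int, kind: str = "uniform", beta: float = 2.0,
                  growth: float = 1.35) -> np.ndarray:
    """Return n+1 points from a to b.

    ``kind``:
      * ``uniform``
      * ``two_sided`` - tanh clustering toward both ends (strength ``beta``)
      * ``geometric`` - spacing growing by ``growth`` away from ``a``
    """
    if n < 1:
        raise ValueError("need at least one interval")
    s = np.linspace(0.0, 1.0, n + 1)
    if kind == "uniform":
        t = s
    elif kind == "two_sided":
        t = 0.5 * (1.0 + np.tanh(beta * (2.0 * s - 1.0)) / np.tanh(beta))
    elif kind == "geometric":
        g = growth
        t = (g ** (n * s) - 1.0) / (g**n - 1.0)
    else:
        raise ValueError(f"unknown grading kind {kind!r}")
    pts = a + (b - a) * t
    pts[0], pts[-1] = a, b
    return pts


@dataclass
class AxisymMesh:
    """Conforming triangulation of the PVS + brain meridional domain.

    ``nodes`` holds reference (r, z) coordinates; ``tris_fluid`` and
    ``tris_solid`` index into it.  ``node_sets`` maps boundary names
    (arteriole_wall, pvs_brain_interface, pial_end, parenchymal_end,
    brain_outer, brain_pial_face, brain_deep_face) to node-id arrays, and
    ``edge_sets`` maps the fluid end boundaries and the interface to (E, 2)
    arrays of node pairs, ordered with increasing r (ends) or z (interface).
    """

    nodes: np.ndarray
    tris_fluid: np.ndarray
    tris_solid: np.ndarray
    node_sets: dict = field(default_factory=dict)
    edge_sets: dict = field(default_factory=dict)
    fluid_node_ids: np.ndarray | None = None
    solid_node_ids: np.ndarray | None = None
    # structured bookkeeping: radial and axial grid lines
    r_pvs: np.ndarray | None = None
    r_brain: np.ndarray | None = None
    z_lines: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def fluid_cross_section_edges(self, z_target: float) -> np.ndarray:
        """Node pairs of the radial fluid grid line nearest to z_target."""
        j = int(np.argmin(np.abs(self.z_lines - z_target)))
        ids = self._fluid_line(j)
        return np.column_stack([ids[:-1], ids[1:]])

    def _fluid_line(self, j: int) -> np.ndarray:
        nrp = len(self.r_pvs) - 1
        nz = len(self.z_lines) - 1
        # fluid nodes are numbered i * (nz+1) + j, i = 0..nrp (r index)
        return np.arange(0, (nrp + 1) * (nz + 1), nz + 1) + j

    def check_valid(self) -> None:
        """Raise with offending cell indices if any triangle is degenerate."""
        for name, tris in (("fluid", self.tris_fluid), ("solid", self.tris_solid)):
            if tris.size == 0:
                continue
            p = self.nodes[tris]
            d1 = p[:, 1] - p[:, 0]
            d2 = p[:, 2] - p[:, 0]
            areas = 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
            bad = np.where(areas <= 0)[0]
            if bad.size:
                raise ValueError(f"non-positive Jacobian in {name} cells {bad[:10].tolist()}")


def _grid_tris(nr: int, nz: int, node_id) -> np.ndarray:
    """Split an (nr x nz) structured grid of quads into CCW triangles.

    ``node_id(i, j)`` maps (radial index, axial index) to a global node id.
    The quad corners are (i,j), (i+1,j), (i+1,j+1), (i,j+1) in (r, z).
    """
    tris = []
    for i in range(nr):
        for j in range(nz):
            n00, n10 = node_id(i, j), node_id(i + 1, j)
            n11, n01 = node_id(i + 1, j + 1), node_id(i, j + 1)
            tris.append([n00, n10, n11])
            tris.append([n00, n11, n01])
    return np.asarray(tris, dtype=np.int64)


def build_mesh(
    params: ModelParameters,
    nr_pvs: int = 10,
    nz: int = 48,
    nr_brain: int = 14,
    beta: float = 2.0,
    growth: float = 1.35,
    include_brain: bool = True,
) -> AxisymMesh:
    """Build the structured PVS (+ optional brain) mesh.

    ``nr_pvs`` radial intervals across the PVS gap (tanh-clustered toward
    both walls), ``nz`` axial intervals shared by the two regions, and
    ``nr_brain`` radial intervals across the brain annulus growing
    geometrically away from the interface.
    """
    if nr_pvs < 4:
        raise ValueError("need at least 4 radial intervals across the PVS width")
    R1, R2, R3, La = params.R1, params.R2, params.R3, params.La

    r_pvs = graded_points(R1, R2, nr_pvs, kind="two_sided", beta=beta)
    z_lines = np.linspace(0.0, La, nz + 1)

    n_fluid = (nr_pvs + 1) * (nz + 1)

    def fid(i, j):  # fluid node (r index i, z index j)
        return i * (nz + 1) + j

    coords = [np.column_stack([np.repeat(r_pvs, nz + 1), np.tile(z_lines, nr_pvs + 1)])]
    tris_fluid = _grid_tris(nr_pvs, nz, fid)

    r_brain = None
    tris_solid = np.empty((0, 3), dtype=np.int64)
    if include_brain:
        r_brain = graded_points(R2, R3, nr_brain, kind="geometric", growth=growth)

        def sid(i, j):  # solid node: i = 0 is the shared interface line
            if i == 0:
                return fid(nr_pvs, j)
            return n_fluid + (i - 1) * (nz + 1) + j

        coords.append(
            np.column_stack(
                [np.repeat(r_brain[1:], nz + 1), np.tile(z_lines, nr_brain)]
            )
        )
        tris_solid = _grid_tris(nr_brain, nz, sid)

    nodes = np.vstack(coords)

    j_all = np.arange(nz + 1)
    i_all = np.arange(nr_pvs + 1)
    interface = np.array([fid(nr_pvs, j) for j in j_all])
    node_sets = {
        "arteriole_wall": np.array([fid(0, j) for j in j_all]),
        "pvs_brain_interface": interface,
        "parenchymal_end": np.array([fid(i, 0) for i in i_all]),
        "pial_end": np.array([fid(i, nz) for i in i_all]),
    }
    edge_sets = {
        "parenchymal_end": np.column_stack(
            [node_sets["parenchymal_end"][:-1], node_sets["parenchymal_end"][1:]]
        ),
        "pial_end": np.column_stack(
            [node_sets["pial_end"][:-1], node_sets["pial_end"][1:]]
        ),
        "pvs_brain_interface": np.column_stack([interface[:-1], interface[1:]]),
    }
    fluid_ids = np.arange(n_fluid)
    solid_ids = np.empty(0, dtype=np.int64)
    if include_brain:
        outer_i = nr_brain
        node_sets["brain_outer"] = np.array(
            [n_fluid + (outer_i - 1) * (nz + 1) + j for j in j_all]
        )
        node_sets["brain_deep_face"] = np.unique(
            np.concatenate(
                [[interface[0]], n_fluid + np.arange(nr_brain - 1) * (nz + 1)]
            )
        )
        node_sets["brain_pial_face"] = np.unique(
            np.concatenate(
                [[interface[nz]], n_fluid + np.arange(nr_brain - 1) * (nz + 1) + nz]
            )
        )
        solid_ids = np.unique(tris_solid)

    mesh = AxisymMesh(
        nodes=nodes,
        tris_fluid=tris_fluid,
        tris_solid=tris_solid,
        node_sets=node_sets,
        edge_sets=edge_sets,
        fluid_node_ids=fluid_ids,
        solid_node_ids=solid_ids,
        r_pvs=r_pvs,
        r_brain=r_brain,
        z_lines=z_lines,
    )
    mesh.check_valid()
    return mesh
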