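"""Fluid-particle trajectories in the deforming PVS.

Particles are advected with the forward-Euler scheme
x_{n+1} = x_n + v(x_n, t_n) dt, where v is the laboratory-frame fluid
velocity linearly interpolated on the current (deformed) triangulation of
a simulation's field snapshots.  A batch of tracer particles is seeded at
the pial (SAS) end of the PVS at a fixed interval to visualize fluid
exchange with the subarachnoid space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.tri import LinearTriInterpolator, Triangulation

from pvsflow.solver import FlowRecord

__all__ = ["ParticleEnsemble", "advect_particles", "forward_euler"]


def forward_euler(positions: np.ndarray, velocity_fn, t0: float, t1: float, dt: float):
    """Generic forward-Euler advection of (n, 2) positions under a velocity
    callback v(positions, t) -> (n, 2).  Returns the trajectory array
    (steps+1, n, 2)."""
    x = np.asarray(positions, dtype=float).copy()
    nsteps = max(int(round((t1 - t0) / dt)), 1)
    traj = np.empty((nsteps + 1,) + x.shape)
    traj[0] = x
    t = t0
    for k in range(nsteps):
        x = x + np.asarray(velocity_fn(x, t)) * dt
        traj[k + 1] = x
        t += dt
    return traj


@dataclass
class ParticleEnsemble:
    """Particle positions over time with seeding metadata.

    ``times`` are the output instants; ``positions`` is a list of (n_k, 2)
    arrays (particle count grows as seed batches are appended);
    ``seed_depth`` holds each particle's initial axial position z (the
    colormap variable); ``batch_times`` the instants at which SAS-side
    batches were appended; ``exited`` flags particles that left through an
    axial end (they are frozen where they exited).
    """

    times: np.ndarray
    positions: list = field(default_factory=list)
    seed_depth: np.ndarray | None = None
    batch_times: list = field(default_factory=list)
    exited: np.ndarray | None = None


def _snapshot_interpolators(record: FlowRecord):
    snaps = record.snapshots
    if not snaps or not snaps.get("t"):
        raise ValueError("record has no field snapshots; rerun with store_every > 0")
    interps = []
    for coords, vr, vz in zip(snaps["coords"], snaps["vr"], snaps["vz"]):
        tri = Triangulation(coords[:, 0], coords[:, 1])
        interps.append((LinearTriInterpolator(tri, vr), LinearTriInterpolator(tri, vz)))
    return np.asarray(snaps["t"]), interps


def advect_particles(
    record: FlowRecord,
    seed_positions: np.ndarray | None = None,
    seed_interval: float = 0.5,
    seed_batch_size: int = 30,
    dt: float | None = None,
    rng: np.random.Generator | None = None,
) -> ParticleEnsemble:
    """Track fluid particles through the snapshots of ``record``.

    ``seed_positions``: initial (n, 2) particle positions; by default a
    uniform grid filling the PVS annulus.  Every ``seed_interval`` seconds
    a batch of ``seed_batch_size`` particles is added just inside the pial
    end to emulate SAS-side fluid entering the exchange region.  ``dt``
    defaults to the snapshot spacing.  Particles advect with forward Euler
    on the piecewise-linear velocity of the nearest-in-time snapshot;
    leaving the domain through an end marks the particle "exited" (not an
    error) and freezes it.
    """
    p = record.params
    rng = rng or np.random.default_rng(0)
    t_snap, interps = _snapshot_interpolators(record)
    if dt is None:
        dt = float(t_snap[1] - t_snap[0]) if len(t_snap) > 1 else record.dt

    if seed_positions is None:
        rr = np.linspace(p.R1 + 0.15 * p.wd, p.R2 - 0.15 * p.wd, 6)
        zz = np.linspace(0.05 * p.La, 0.95 * p.La, 25)
        R, Z = np.meshgrid(rr, zz)
        seed_positions = np.column_stack([R.ravel(), Z.ravel()])
    x = np.asarray(seed_positions, dtype=float).copy()
    depth = x[:, 1].copy()
    exited = np.zeros(len(x), dtype=bool)

    times = []
    positions = []
    batch_times = []
    t0, t1 = float(t_snap[0]), float(t_snap[-1])
    nsteps = max(int(round((t1 - t0) / dt)), 1)
    next_batch = seed_interval
    for k in range(nsteps + 1):
        t = t0 + k * dt
        if t + 1e-12 >= next_batch:
            xb = np.column_stack([
                rng.uniform(p.R1 + 0.1 * p.wd, p.R2 - 0.1 * p.wd, seed_batch_size),
                np.full(seed_batch_size, 0.985 * p.La),
            ])
            x = np.vstack([x, xb])
            depth = np.concatenate([depth, xb[:, 1]])
            exited = np.concatenate([exited, np.zeros(seed_batch_size, dtype=bool)])
            batch_times.append(t)
            next_batch += seed_interval
        times.append(t)
        positions.append(x.copy())
        if k == nsteps:
            break
        i = int(np.argmin(np.abs(t_snap - t)))
        fvr, fvz = interps[i]
        vr = np.asarray(fvr(x[:, 0], x[:, 1]))
        vz = np.asarray(fvz(x[:, 0], x[:, 1]))
        bad = ~np.isfinite(vr) | ~np.isfinite(vz)
        vr[bad] = 0.0
        vz[bad] = 0.0
        active = ~exited
        x[active, 0] += vr[active] * dt
        x[active, 1] += vz[active] * dt
        out = (x[:, 1] < 0.0) | (x[:, 1] > p.La)
        newly = out & ~exited
        x[newly, 1] = np.clip(x[newly, 1], 0.0, p.La)
        exited |= out

    return ParticleEnsemble(
        times=np.asarray(times),
        positions=positions,
        seed_depth=depth,
        batch_times=batch_times,
        exited=exited,
    )
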