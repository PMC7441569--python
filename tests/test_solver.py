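"""Time-dependent simulations: conservation, limits, coupling behaviour."""

import numpy as np
import pytest

from pvsflow.metrics import mass_conservation_error
from pvsflow.parameters import default_parameters
from pvsflow.solver import run_coupled, run_rigid
from pvsflow.wall_motion import WallMotion


@pytest.fixture(scope="module")
def p():
    return default_parameters()


class _CompactPulse:
    """C1 wall pulse a sin^2(pi t / T0) that ends exactly at T0; afterwards
    the wall is at rest and the coupled system must dissipate."""

    kind = "pulse"

    def __init__(self, amplitude, T0, La):
        self.amplitude = amplitude
        self.T0 = T0
        self.La = La
        self.duration = T0

    def displacement(self, z, t):
        z = np.asarray(z, dtype=float)
        if t >= self.T0 or t <= 0:
            return np.zeros(z.shape)
        val = self.amplitude * np.sin(np.pi * t / self.T0) ** 2
        return np.broadcast_to(val, z.shape).copy()

    def velocity(self, z, t):
        z = np.asarray(z, dtype=float)
        if t >= self.T0 or t <= 0:
            return np.zeros(z.shape)
        val = (self.amplitude * np.pi / self.T0) * np.sin(2 * np.pi * t / self.T0)
        return np.broadcast_to(val, z.shape).copy()


def test_zero_wall_motion_keeps_everything_at_rest(p):
    motion = WallMotion(kind="sinusoid", amplitude=0.0, La=p.La, f=1.0, duration=0.05)
    rec = run_coupled(p, motion, nr_pvs=6, nz=12, nr_brain=8, dt=0.01, duration=0.05)
    assert rec.peak_speed == 0.0
    assert np.allclose(rec.p_interface, 0.0)
    assert np.allclose(rec.ur_interface, 0.0)
    assert np.allclose(rec.q_pial, 0.0)


def test_rigid_heartbeat_oscillatory_flow_scale(rigid_heartbeat_record):
    """Heartbeat pulsation against a rigid outer wall drives oscillatory
    flow with peak speeds of a few hundred um/s and peak pressures around
    ten mmHg, with no appreciable net drift."""
    rec = rigid_heartbeat_record
    assert 250e-6 < rec.peak_speed < 360e-6
    peak_mmHg = np.abs(rec.p_interface).max() / 133.322
    assert 8.5 < peak_mmHg < 12.0
    # net drift is orders of magnitude below the oscillation
    assert abs(rec.q_pial.mean()) < 1e-4 * np.abs(rec.q_pial).max()


def test_mass_conservation_heartbeat(rigid_heartbeat_record, coupled_heartbeat_record):
    assert mass_conservation_error(rigid_heartbeat_record) < 1e-3
    assert mass_conservation_error(coupled_heartbeat_record) < 1e-3


def test_rigid_velocity_linear_in_amplitude(p):
    """For small pulsation amplitudes the rigid-mode response is linear in
    b1: doubling the amplitude doubles the boundary fluxes."""
    kw = dict(nr_pvs=6, nz=12, dt=5e-4, duration=0.02)
    r1 = run_rigid(p, WallMotion.heartbeat(p), **kw)
    r2 = run_rigid(p.with_overrides(b1=2.0),
                   WallMotion.heartbeat(p.with_overrides(b1=2.0)), **kw)
    scale = np.abs(r1.q_pial).max()
    # the residual deviation is the genuine quadratic (moving-geometry)
    # correction, well below 1% at this amplitude
    assert np.allclose(r2.q_pial, 2 * r1.q_pial, atol=1e-2 * scale)


def test_reversed_drive_mirrors_fluxes(p):
    """The Robin outlets act symmetrically for inflow and outflow: negating
    the wall motion negates the flux history (up to tiny nonlinear terms)."""

    class Neg:
        kind = "sinusoid"

        def __init__(self, m):
            self.m = m
            self.duration = m.duration

        def displacement(self, z, t):
            return -self.m.displacement(z, t)

        def velocity(self, z, t):
            return -self.m.velocity(z, t)

    m = WallMotion.heartbeat(p)
    kw = dict(nr_pvs=6, nz=12, dt=5e-4, duration=0.02)
    r_pos = run_rigid(p, m, **kw)
    r_neg = run_rigid(p, Neg(m), **kw)
    scale = np.abs(r_pos.q_pial).max()
    # asymmetry is the quadratic geometric correction, < 1% at 0.06 um
    assert np.allclose(r_neg.q_pial, -r_pos.q_pial, atol=1e-2 * scale)


def test_free_outlet_pressure_peaks_mid_channel(p):
    """Without end resistances the pressure must vanish at both ends, so
    its profile peaks in the channel interior."""
    rec = run_rigid(p, WallMotion.heartbeat(p), outlets="free",
                    nr_pvs=6, nz=24, dt=5e-4, duration=0.05)
    prof = np.abs(rec.peak_pressure_profile())
    k = int(np.argmax(prof))
    assert 4 < k < 20
    assert prof[0] < 0.25 * prof[k] and prof[-1] < 0.25 * prof[k]


def test_long_arteriole_peristaltic_pumping(p):
    """When the channel spans a full pulse wavelength (La = 0.1 m) the
    travelling wave pumps strongly in its direction of travel (mean
    downstream speed ~143 um/s) at the cost of physically implausible
    pressures (~2e5 mmHg) -- the unphysiological-geometry regime."""
    from pvsflow.metrics import mean_downstream_speed

    long_p = p.with_overrides(La=0.1)
    rec = run_rigid(long_p, WallMotion.heartbeat(long_p), nr_pvs=6, nz=200,
                    dt=2e-4, duration=0.1, outlets="free")
    assert mean_downstream_speed(rec) == pytest.approx(143.2, rel=0.15)
    assert np.abs(rec.p_interface).max() / 133.322 > 1e5
    assert 1.5e4 < rec.peak_speed * 1e6 < 3e4


def test_energy_decays_after_wall_pulse(p):
    """Once the wall comes to rest, the total tissue energy (elastic +
    kinetic) can only be dissipated by the fluid."""
    pulse = _CompactPulse(0.2e-6, 0.05, p.La)
    rec = run_coupled(p, pulse, nr_pvs=6, nz=12, nr_brain=8, dt=2.5e-3,
                      duration=0.3)
    E = rec.energy_elastic + rec.energy_kinetic
    after = E[rec.times > 0.06]
    assert after[0] > 0
    assert np.all(np.diff(after) <= 1e-3 * after[0])
    assert after[-1] < 0.2 * after[0]


def test_coupled_heartbeat_interface_response(coupled_heartbeat_record, p):
    """The tissue follows the wall so as to nearly conserve the trapped
    fluid volume: interface excursion ~ (R1/R2) x wall amplitude."""
    rec = coupled_heartbeat_record
    peak_ur = np.abs(rec.ur_interface).max()
    expected = 0.06e-6 * p.R1 / p.R2
    assert peak_ur == pytest.approx(expected, rel=0.25)


def test_invalid_options_rejected(p):
    m = WallMotion.heartbeat(p)
    with pytest.raises(ValueError):
        run_rigid(p, m, outlets="open")
    from pvsflow.solver import Simulation

    with pytest.raises(ValueError):
        Simulation(p, m, mode="loose")
    with pytest.raises(ValueError):
        Simulation(p, m, outlet_reference="harmonic")
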