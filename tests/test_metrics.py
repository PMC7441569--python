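"""Transport metrics on constructed flow records."""

import numpy as np
import pytest

from pvsflow.metrics import (
    dimensionless_numbers,
    mean_downstream_speed,
    periodic_mean_downstream_speed,
    powerlaw_fit,
    volume_exchange_fraction,
)
from pvsflow.parameters import default_parameters
from pvsflow.solver import FlowRecord


def make_record(times, q_pial, q_deep, q_f50=None, volume=None, params=None):
    p = params or default_parameters()
    n = len(times)
    zi = np.linspace(0, p.La, 5)
    return FlowRecord(
        params=p, times=np.asarray(times, float),
        q_pial=np.asarray(q_pial, float), q_deep=np.asarray(q_deep, float),
        q_f50=np.asarray(q_f50 if q_f50 is not None else q_pial, float),
        volume=np.asarray(volume if volume is not None else np.full(n, p.pvs_volume)),
        mean_vz=np.zeros(n), peak_speed=0.0,
        p_interface=np.zeros((n, 5)), ur_interface=np.zeros((n, 5)),
        z_interface=zi, wall_disp=np.zeros(n),
        mass_residual=np.zeros(n),
    )


@pytest.fixture(scope="module")
def p():
    return default_parameters()


class TestMeanDownstreamSpeed:
    def test_uniform_downstream_field(self, p):
        """v_z = -1 um/s everywhere: deep outflow +A, pial inflow -A."""
        A = p.annulus_area
        t = np.linspace(0.01, 1.0, 100)
        rec = make_record(t, q_pial=-1e-6 * A * np.ones(100),
                          q_deep=+1e-6 * A * np.ones(100))
        assert mean_downstream_speed(rec) == pytest.approx(1.0)

    def test_standing_oscillation_averages_to_zero(self, p):
        A = p.annulus_area
        t = np.arange(1, 1001) * 1e-3
        q = 1e-6 * A * np.sin(2 * np.pi * 5 * t)
        rec = make_record(t, q_pial=q, q_deep=q)  # both ends in phase
        assert abs(mean_downstream_speed(rec)) < 1e-9

    def test_window_outside_record_rejected(self, p):
        t = np.linspace(0.01, 1.0, 10)
        rec = make_record(t, np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError, match="window"):
            mean_downstream_speed(rec, window=(0.0, 2.0))


class TestVolumeExchange:
    def test_zero_flow_gives_zero(self, p):
        t = np.linspace(0.01, 1.0, 10)
        rec = make_record(t, np.zeros(10), np.zeros(10))
        assert volume_exchange_fraction(rec) == 0.0

    def test_known_expelled_volume(self, p):
        """A rectangular outflow pulse expelling W m^3 gives
        Q_f = W / (zeta V_geom)."""
        dt = 0.01
        t = np.arange(1, 201) * dt
        q = np.zeros(200)
        q[50:100] = 2e-15  # m^3/s for 0.5 s -> W = 1e-15 m^3
        rec = make_record(t, q_pial=q, q_deep=np.zeros(200))
        W = np.trapezoid(np.concatenate([[0], q]), np.concatenate([[0], t]))
        expected = W / (p.zeta * p.pvs_volume)
        assert volume_exchange_fraction(rec) == pytest.approx(expected, rel=1e-6)
        assert volume_exchange_fraction(rec, percent=True) == pytest.approx(
            100 * expected, rel=1e-6)
        assert volume_exchange_fraction(rec, fluid_volume=False) == pytest.approx(
            expected * p.zeta, rel=1e-6)

    def test_net_inflow_clips_at_zero(self, p):
        t = np.arange(1, 11) * 0.1
        rec = make_record(t, q_pial=-1e-15 * np.ones(10), q_deep=np.zeros(10))
        assert volume_exchange_fraction(rec) == 0.0

    def test_both_ends_accounting(self, p):
        t = np.arange(1, 101) * 0.01
        q = np.full(100, 1e-15)
        rec = make_record(t, q_pial=q, q_deep=q)
        assert volume_exchange_fraction(rec, ends=("pial", "deep")) == pytest.approx(
            2 * volume_exchange_fraction(rec), rel=1e-9)


class TestDimensionlessNumbers:
    def test_zero_flow(self, p):
        t = np.linspace(0.01, 1.0, 10)
        rec = make_record(t, np.zeros(10), np.zeros(10))
        dn = dimensionless_numbers(rec)
        assert dn == (0.0, 0.0, 0.0)

    def test_peak_flux_reduction(self, p):
        t = np.arange(1, 101) * 0.01
        q0 = 1e-14 * np.sin(2 * np.pi * t)
        q50 = 0.25 * q0
        rec = make_record(t, q_pial=q0, q_deep=np.zeros(100), q_f50=q50)
        dn = dimensionless_numbers(rec)
        A = p.annulus_area
        assert dn.Pe_0 == pytest.approx(2 * 1e-14 * p.wd / (p.D * A), rel=1e-6)
        assert dn.Pe_50 == pytest.approx(dn.Pe_0 / 4, rel=1e-6)
        assert dn.Re == pytest.approx(dn.Pe_0 * p.D * p.rho_f / p.mu_f, rel=1e-9)
        # outward events decay with depth
        assert dn.Pe_0 >= dn.Pe_50


class TestPowerLaw:
    def test_exact_loglinear_data_recovered(self):
        f = np.array([0.05, 0.2, 1.0, 5.0, 10.0])
        fit = powerlaw_fit(f, 2.0 * f**-0.5)
        assert fit.prefactor == pytest.approx(2.0, rel=1e-12)
        assert fit.exponent == pytest.approx(-0.5, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            powerlaw_fit([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            powerlaw_fit([1.0, -2.0, 3.0], [1.0, 2.0, 3.0])


class TestPeriodicSpeed:
    def test_short_record_rejected(self, p):
        t = np.arange(1, 101) * 1e-3  # one cycle at 10 Hz
        rec = make_record(t, np.zeros(100), np.zeros(100))
        with pytest.raises(ValueError, match="cycles"):
            periodic_mean_downstream_speed(rec, period=0.1)

    def test_storage_transient_removed(self, p):
        """Cycle means contaminated by an exponentially decaying storage
        flux: the regression against the volume growth rate recovers the
        asymptotic through-flow."""
        A = p.annulus_area
        T, n_cyc, per = 0.1, 8, 100
        t = np.arange(1, n_cyc * per + 1) * (T / per)
        true_q = 5e-19  # asymptotic downstream flow rate, m^3/s
        storage = 2e-16 * np.exp(-t / 0.4)
        q_deep = true_q - 0.05 * storage + 1e-16 * np.sin(2 * np.pi * t / T)
        q_pial = -true_q - 0.95 * storage - 1e-16 * np.sin(2 * np.pi * t / T)
        vol = p.pvs_volume + np.cumsum(storage) * (T / per)
        rec = make_record(t, q_pial=q_pial, q_deep=q_deep, volume=vol)
        est = periodic_mean_downstream_speed(rec, period=T)
        assert est == pytest.approx(true_q / A * 1e6, rel=0.05)
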