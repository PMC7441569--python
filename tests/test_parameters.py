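"""Parameter table, derived quantities and the annulus resistance model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_bvp

from pvsflow.parameters import (
    ModelParameters,
    annular_poiseuille_resistance,
    default_parameters,
    lame_lambda,
    outlet_reference_resistance,
    pvs_reference_resistance,
)


class TestDefaults:
    def test_default_column(self):
        p = default_parameters()
        assert p.R1 == pytest.approx(12e-6)
        assert p.wd == pytest.approx(3e-6)
        assert p.La == pytest.approx(250e-6)
        assert p.R3 == pytest.approx(150e-6)
        assert p.zeta == 0.8
        assert p.k_s == pytest.approx(2e-14)
        assert p.mu_s == pytest.approx(4e3)
        assert p.f == 10.0
        assert p.c == 1.0
        assert p.D == pytest.approx(1.4e-10)
        assert p.r_sas == 0.01
        assert p.r_par == 10.0

    def test_wavelength_is_c_over_f(self):
        p = default_parameters()
        assert p.lambda_wave == pytest.approx(0.1)
        assert p.lambda_wave * p.f == pytest.approx(p.c, rel=1e-15)

    def test_geometric_pvs_volume(self):
        # pi ((R1+wd)^2 - R1^2) La = 6.36e4 um^3 for the defaults
        p = default_parameters()
        assert p.pvs_volume == pytest.approx(6.36e4 * 1e-18, rel=1e-3)


class TestLameLambda:
    @pytest.mark.parametrize(
        "mu, nu, expected",
        [(4e3, 0.45, 36e3), (7.7e3, 0.0, 0.0), (1e3, 0.25, 1e3)],
    )
    def test_values(self, mu, nu, expected):
        assert lame_lambda(mu, nu) == pytest.approx(expected)

    def test_incompressible_rejected(self):
        with pytest.raises(ValueError, match="compressible"):
            lame_lambda(4e3, 0.5)


class TestResistance:
    def test_default_darcy_resistance(self):
        # mu zeta La / (k A) with A = pi * 81e-12 m^2
        p = default_parameters()
        assert pvs_reference_resistance(p) == pytest.approx(3.93e16, rel=2e-3)

    def test_linear_in_length(self):
        p = default_parameters()
        p2 = p.with_overrides(La=2 * p.La)
        assert pvs_reference_resistance(p2) == pytest.approx(
            2 * pvs_reference_resistance(p), rel=1e-12)

    def test_navier_stokes_limit_matches_bvp_oracle(self):
        """The closed-form annular Poiseuille resistance must agree with an
        independent numerical solution of the steady axial-flow two-point
        boundary-value problem mu (v'' + v'/r) = dp/dz, v(R1)=v(R2)=0."""
        p = default_parameters().with_overrides(k_s=math.inf)
        dpdz = -1.0  # Pa/m

        def ode(r, y):
            return np.vstack([y[1], dpdz / p.mu_f - y[1] / r])

        def bc(ya, yb):
            return np.array([ya[0], yb[0]])

        r = np.linspace(p.R1, p.R2, 200)
        sol = solve_bvp(ode, bc, r, np.zeros((2, r.size)), tol=1e-10)
        assert sol.success
        rr = np.linspace(p.R1, p.R2, 4001)
        v = sol.sol(rr)[0]
        Q = np.trapezoid(2 * np.pi * rr * v, rr)
        R_oracle = (-dpdz * p.La) / Q
        assert pvs_reference_resistance(p) == pytest.approx(R_oracle, rel=1e-4)

    def test_outlet_reference_keeps_physiological_value_in_ns_limit(self):
        p = default_parameters()
        pn = p.with_overrides(k_s=math.inf)
        assert outlet_reference_resistance(pn) == pytest.approx(
            pvs_reference_resistance(p))
        # and the open-channel value is ~30x smaller
        assert pvs_reference_resistance(pn) < 0.1 * pvs_reference_resistance(p)

    @given(k=st.floats(1e-15, 1e-12), factor=st.floats(1.01, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_monotone_decreasing_in_permeability_and_width(self, k, factor):
        p = default_parameters().with_overrides(k_s=k)
        assert pvs_reference_resistance(p.with_overrides(k_s=k * factor)) < \
            pvs_reference_resistance(p)
        wider = p.with_overrides(wd=p.wd * factor if p.wd * factor < 10e-6 else 10e-6)
        assert pvs_reference_resistance(wider) < pvs_reference_resistance(p)

    def test_degenerate_width_rejected(self):
        with pytest.raises(ValueError):
            ModelParameters(wd=-1e-6)


class TestValidation:
    def test_invariants_rejected_with_messages(self):
        with pytest.raises(ValueError, match="R3"):
            ModelParameters(R3=10e-6)
        with pytest.raises(ValueError, match="porosity"):
            ModelParameters(zeta=1.2)
        with pytest.raises(ValueError, match="Poisson"):
            ModelParameters(nu=0.6)

    def test_range_check_flags_out_of_table_values(self):
        msgs = ModelParameters(R1=30e-6, R3=160e-6).check_ranges()
        assert any("R1" in m for m in msgs)
        assert ModelParameters().check_ranges() == []
        # the long-arteriole geometry is flagged but constructible
        long = ModelParameters(La=0.1)
        assert any("La" in m for m in long.check_ranges())

    def test_json_roundtrip(self, tmp_path):
        p = default_parameters().with_overrides(k_s=math.inf, r_sas=0.1)
        path = tmp_path / "params.json"
        p.to_json(path)
        q = ModelParameters.from_json(path)
        assert q.navier_stokes
        assert q.r_sas == 0.1

    def test_json_rejects_unknown_and_out_of_range(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"R1": 3e-5}')
        with pytest.raises(ValueError, match="outside accepted"):
            ModelParameters.from_json(path)
        path.write_text('{"radius": 1}')
        with pytest.raises(ValueError, match="unknown"):
            ModelParameters.from_json(path)
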