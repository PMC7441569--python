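"""Physical and geometric parameters of the paravascular-space model.

All quantities are stored internally in SI units.  The constructors accept
the units in which the quantities are usually quoted (micrometres for
lengths, kilopascals for the tissue shear modulus, cm^2/s for diffusivity)
and convert once.  The parameter set covers the fluid (CSF), the porous
annulus (PVS), the brain-tissue solid, the arteriolar wall motion, and the
lumped hydraulic resistances that close the two axial ends of the PVS.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

__all__ = [
    "ModelParameters",
    "default_parameters",
    "lame_lambda",
    "pvs_reference_resistance",
    "annular_poiseuille_resistance",
    "TABLE_RANGES",
]

_UM = 1e-6  # metres per micrometre

#: Accepted ranges in interface units (µm, kPa, Hz, m/s, dimensionless),
#: used by :meth:`ModelParameters.check_ranges`.
TABLE_RANGES = {
    "R1_um": (5.0, 20.0),
    "La_um": (250.0, 500.0),
    "wd_um": (2.0, 10.0),
    "zeta": (0.5, 0.9),
    "k_s": (2e-15, 7e-13),
    "R3_um": (100.0, 200.0),
    "mu_s_kPa": (1.0, 8.0),
    "b1": (0.5, 2.0),
    "f": (7.0, 14.0),
    "c": (0.5, 10.0),
}


def lame_lambda(mu_s: float, nu: float) -> float:
    """First Lame parameter of a compressible solid, ``2*nu*mu/(1-2*nu)``.

    ``mu_s`` is the shear modulus (any unit; the result carries the same
    unit), ``nu`` the Poisson ratio.  Raises for ``nu >= 0.5``, where the
    compressible model does not apply, and for negative ``nu``.
    """
    if not 0.0 <= nu < 0.5:
        raise ValueError(
            f"Poisson ratio nu={nu} outside [0, 0.5); the compressible "
            "Saint-Venant-Kirchhoff model requires nu < 0.5"
        )
    return 2.0 * nu * mu_s / (1.0 - 2.0 * nu)


def annular_poiseuille_resistance(R1: float, R2: float, La: float, mu_f: float) -> float:
    """Hydraulic resistance (Pa s/m^3) of steady Poiseuille flow in a
    concentric annulus of inner radius ``R1``, outer radius ``R2`` and
    length ``La`` (all SI).

    Classical closed form: Q = pi dp/(8 mu La) * [R2^4 - R1^4
    - (R2^2 - R1^2)^2 / ln(R2/R1)].
    """
    if not 0 < R1 < R2:
        raise ValueError("need 0 < R1 < R2 for an annulus")
    bracket = R2**4 - R1**4 - (R2**2 - R1**2) ** 2 / math.log(R2 / R1)
    return 8.0 * mu_f * La / (math.pi * bracket)


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter set, SI units.

    Geometry: ``R1`` arteriolar radius, ``wd`` PVS gap width, ``La`` PVS
    length, ``R3`` outer radius of the simulated brain-tissue annulus (all
    metres).  Fluid: viscosity ``mu_f`` (Pa s), density ``rho_f`` (kg/m^3),
    porosity ``zeta`` and permeability ``k_s`` (m^2; ``inf`` selects the
    Navier-Stokes limit).  Solid: shear modulus ``mu_s`` (Pa), Poisson ratio
    ``nu``, density ``rho_s``.  Wall motion: peak-to-peak pulsation
    amplitude ``b1`` (percent of R1), frequency ``f`` (Hz), pulse-wave speed
    ``c`` (m/s).  Transport: solute diffusivity ``D`` (m^2/s).  Outlets:
    ``r_sas`` and ``r_par``, the SAS and parenchymal resistances as
    multiples of the PVS reference resistance.
    """

    R1: float = 12e-6
    wd: float = 3e-6
    La: float = 250e-6
    R3: float = 150e-6
    mu_f: float = 1e-3
    rho_f: float = 1000.0
    zeta: float = 0.8
    k_s: float = 2e-14
    mu_s: float = 4e3
    nu: float = 0.45
    rho_s: float = 1000.0
    b1: float = 1.0
    f: float = 10.0
    c: float = 1.0
    D: float = 1.4e-10
    r_sas: float = 0.01
    r_par: float = 10.0

    def __post_init__(self) -> None:
        if self.R1 <= 0 or self.wd <= 0 or self.La <= 0:
            raise ValueError("R1, wd and La must all be positive")
        if self.R3 <= self.R1 + self.wd:
            raise ValueError(
                f"brain outer radius R3={self.R3} must exceed R1+wd={self.R1 + self.wd}"
            )
        if not 0.0 < self.zeta < 1.0:
            raise ValueError(f"porosity zeta={self.zeta} must lie in (0, 1)")
        if not self.k_s > 0:
            raise ValueError(f"permeability k_s={self.k_s} must be positive (inf allowed)")
        if not 0.0 < self.nu < 0.5:
            raise ValueError(f"Poisson ratio nu={self.nu} must lie in (0, 0.5)")
        if self.r_sas <= 0 or self.r_par <= 0:
            raise ValueError("resistance ratios r_sas, r_par must be positive")
        if self.f <= 0 or self.c <= 0:
            raise ValueError("pulsation frequency f and wave speed c must be positive")

    # -- derived quantities -------------------------------------------------

    @property
    def R2(self) -> float:
        """Outer radius of the PVS annulus (brain-PVS interface), m."""
        return self.R1 + self.wd

    @property
    def navier_stokes(self) -> bool:
        """True when the permeability is infinite (no Brinkman drag)."""
        return math.isinf(self.k_s)

    @property
    def lambda_wave(self) -> float:
        """Pulse wavelength c/f, m."""
        return self.c / self.f

    @property
    def lame_lambda_s(self) -> float:
        """First Lame parameter of the brain tissue, Pa."""
        return lame_lambda(self.mu_s, self.nu)

    @property
    def annulus_area(self) -> float:
        """Cross-sectional area of the PVS annulus, m^2."""
        return math.pi * (self.R2**2 - self.R1**2)

    @property
    def pvs_volume(self) -> float:
        """Geometric volume of the PVS annulus pi*(R2^2-R1^2)*La, m^3."""
        return self.annulus_area * self.La

    @property
    def heartbeat_amplitude(self) -> float:
        """Peak radial wall excursion for heartbeat pulsation, m.

        ``b1`` is peak-to-peak percent of R1, so the peak amplitude is
        (b1/2)% of R1 (0.06 um for the defaults).
        """
        return self.R1 * self.b1 / 200.0

    @property
    def hyperemia_amplitude(self) -> float:
        """Peak radial wall excursion for functional hyperemia, m (15% of R1)."""
        return 0.15 * self.R1

    @property
    def sinusoid_amplitude(self) -> float:
        """Peak excursion of the 4% peak-to-peak sweep sinusoid, m (2% of R1)."""
        return 0.02 * self.R1

    # -- constructors / IO --------------------------------------------------

    @classmethod
    def from_physiological(
        cls,
        R1_um: float = 12.0,
        wd_um: float = 3.0,
        La_um: float = 250.0,
        R3_um: float = 150.0,
        mu_s_kPa: float = 4.0,
        D_cm2_s: float = 1.4e-6,
        **si_kwargs,
    ) -> "ModelParameters":
        """Build from the units the quantities are usually quoted in."""
        return cls(
            R1=R1_um * _UM,
            wd=wd_um * _UM,
            La=La_um * _UM,
            R3=R3_um * _UM,
            mu_s=mu_s_kPa * 1e3,
            D=D_cm2_s * 1e-4,
            **si_kwargs,
        )

    def check_ranges(self) -> list[str]:
        """Return messages for every parameter outside its accepted range.

        The ranges reflect reported physiological spreads; a value outside
        them is not necessarily wrong (the long-arteriole pumping experiment
        deliberately uses La = 0.1 m) but callers loading user configs
        should surface the messages.
        """
        quoted = {
            "R1_um": self.R1 / _UM,
            "La_um": self.La / _UM,
            "wd_um": self.wd / _UM,
            "zeta": self.zeta,
            "k_s": self.k_s,
            "R3_um": self.R3 / _UM,
            "mu_s_kPa": self.mu_s / 1e3,
            "b1": self.b1,
            "f": self.f,
            "c": self.c,
        }
        msgs = []
        for name, (lo, hi) in TABLE_RANGES.items():
            v = quoted[name]
            if name == "k_s" and math.isinf(v):
                continue  # Navier-Stokes limit is a legitimate mode
            if not lo <= v <= hi:
                msgs.append(f"{name}={v:g} outside accepted range [{lo:g}, {hi:g}]")
        return msgs

    def with_overrides(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        if math.isinf(d["k_s"]):
            d["k_s"] = "inf"
        return d

    @classmethod
    def from_json(cls, path: str | Path, strict_ranges: bool = True) -> "ModelParameters":
        """Load a JSON config whose keys mirror the dataclass field names.

        ``k_s`` may be the string "inf".  With ``strict_ranges`` any value
        outside the accepted range raises a ``ValueError`` listing every
        violation.
        """
        data = json.loads(Path(path).read_text())
        if str(data.get("k_s", "")).lower() in {"inf", "infinite", "infinity"}:
            data["k_s"] = math.inf
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown parameter names in config: {sorted(unknown)}")
        params = cls(**data)
        if strict_ranges:
            msgs = params.check_ranges()
            if msgs:
                raise ValueError("parameters outside accepted ranges: " + "; ".join(msgs))
        return params

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def default_parameters() -> ModelParameters:
    """The default parameter column: R1 = 12 um, wd = 3 um, La = 250 um,
    R3 = 150 um, zeta = 0.8, k_s = 2e-14 m^2, mu_s = 4 kPa, nu = 0.45,
    b1 = 1%, f = 10 Hz, c = 1 m/s, D = 1.4e-6 cm^2/s, r_sas = 0.01,
    r_par = 10."""
    return ModelParameters()


def pvs_reference_resistance(params: ModelParameters) -> float:
    """Steady hydraulic resistance of the PVS annulus, Pa s/m^3.

    This is the reference scale that the lumped SAS and parenchymal outlet
    resistances multiply (``r_sas`` and ``r_par``).  For finite permeability
    it is the Darcy resistance of the annulus,

        R_PVS = mu_f * zeta * La / (k_s * A),   A = pi (R2^2 - R1^2),

    the unique steady-state resistance consistent with drag-dominated
    Darcy-Brinkman flow.  In the Navier-Stokes limit (infinite k_s) it is
    the classical concentric-annulus Poiseuille resistance.
    """
    if params.wd <= 0:
        raise ValueError("degenerate geometry: PVS width must be positive")
    if params.navier_stokes:
        return annular_poiseuille_resistance(params.R1, params.R2, params.La, params.mu_f)
    return params.mu_f * params.zeta * params.La / (params.k_s * params.annulus_area)


#: Table-default PVS permeability, m^2 (used as the physiological reference
#: when the run itself idealizes the permeability away).
DEFAULT_K_S = 2e-14


def outlet_reference_resistance(params: ModelParameters) -> float:
    """Reference PVS resistance from which the lumped SAS and parenchymal
    outlet resistances are scaled (r_sas and r_par multiples), Pa s/m^3.

    The outlets represent anatomy outside the PVS, so their values are
    anchored to the physiological Darcy resistance of the annulus: for a
    finite permeability this coincides with
    :func:`pvs_reference_resistance`; in the Navier-Stokes limit the
    reference keeps the Table-default permeability rather than dropping to
    the (30x smaller) open-channel Poiseuille value -- idealizing the PVS
    interior does not alter the surrounding flow paths.
    """
    if params.wd <= 0:
        raise ValueError("degenerate geometry: PVS width must be positive")
    k_eff = DEFAULT_K_S if params.navier_stokes else params.k_s
    return params.mu_f * params.zeta * params.La / (k_eff * params.annulus_area)
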