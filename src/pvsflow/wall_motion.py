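"""Prescribed radial motion of the arteriolar wall.

Three driving waveforms are supported:

``heartbeat``
    A sinusoid of peak amplitude (b1/2)% of R1 travelling along the wall at
    the pulse-wave speed c, entering at the pial end (z = La) and moving
    toward the parenchyma (z = 0).  For the default geometry the wavelength
    (0.1 m) dwarfs the PVS length, so the whole wall moves nearly in phase
    (phase lag 2*pi*La/lambda ~ 0.016 rad end to end); the initial
    displacement is exactly zero at the pial end and O(a*La/lambda) ~ 1 nm
    elsewhere.

``hyperemia``
    A spatially uniform, gamma-function-shaped dilation
    u(t) = dR_max (t/tp)^k exp(k (1 - t/tp)) with peak dR_max = 0.15 R1
    near tp = 1.2 s, decayed to well below 10% of peak by t = 10 s.
    Functional hyperemic dilations take one to a few seconds to peak and
    last several seconds; k = 2 gives that time course.

``sinusoid``
    A spatially uniform sinusoid of 4% peak-to-peak radius change (peak
    amplitude 2% of R1) used for the frequency sweep.

All displacements are radial; the wall has no axial motion.  The no-slip
fluid velocity at the wall is the analytic time derivative provided by
:meth:`WallMotion.velocity`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from pvsflow.parameters import ModelParameters

__all__ = [
    "WallMotion",
    "heartbeat_displacement",
    "hyperemia_displacement",
    "sinusoid_displacement",
]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class WallMotion:
    """Radial wall displacement u_wall(z, t) and its time derivative.

    ``amplitude`` is the peak radial excursion in metres.  ``f`` and ``c``
    apply to the periodic kinds; ``t_peak`` and ``shape_k`` to hyperemia.
    ``La`` fixes the pial end z = La where the travelling heartbeat wave
    enters.
    """

    kind: str  # heartbeat | hyperemia | sinusoid
    amplitude: float
    La: float
    f: float = 10.0
    c: float = 1.0
    t_peak: float = 1.2
    shape_k: float = 2.0
    duration: float = 0.1

    def __post_init__(self):
        if self.kind not in {"heartbeat", "hyperemia", "sinusoid"}:
            raise ValueError(f"unknown wall-motion kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    # -- factories ----------------------------------------------------------

    @classmethod
    def heartbeat(cls, params: ModelParameters, La: float | None = None) -> "WallMotion":
        """Travelling pulsation wave; ``La`` may override the PVS length
        (the long-arteriole pumping experiment uses La = 0.1 m)."""
        La = params.La if La is None else La
        return cls(
            kind="heartbeat",
            amplitude=params.heartbeat_amplitude,
            La=La,
            f=params.f,
            c=params.c,
            duration=1.0 / params.f,
        )

    @classmethod
    def hyperemia(cls, params: ModelParameters, duration: float = 10.0) -> "WallMotion":
        return cls(
            kind="hyperemia",
            amplitude=params.hyperemia_amplitude,
            La=params.La,
            t_peak=1.2,
            shape_k=2.0,
            duration=duration,
        )

    @classmethod
    def sinusoid(cls, params: ModelParameters, f: float) -> "WallMotion":
        if not 0.05 <= f <= 10.0:
            raise ValueError(f"sweep frequency f={f} Hz outside [0.05, 10] Hz")
        return cls(
            kind="sinusoid",
            amplitude=params.sinusoid_amplitude,
            La=params.La,
            f=f,
            duration=1.0 / f,
        )

    # -- evaluation ----------------------------------------------------------

    def displacement(self, z, t):
        """Radial wall displacement (m) at axial position(s) z and time t."""
        z = np.asarray(z, dtype=float)
        a = self.amplitude
        if self.kind == "heartbeat":
            # wave enters at the pial end (z = La), travels toward z = 0
            phase = _TWO_PI * self.f * (t - (self.La - z) / self.c)
            return a * np.sin(phase)
        if self.kind == "sinusoid":
            return np.broadcast_to(a * math.sin(_TWO_PI * self.f * t), z.shape).copy()
        # hyperemia: gamma-function time course, uniform in z
        s = max(float(t), 0.0) / self.t_peak
        k = self.shape_k
        val = a * s**k * math.exp(k * (1.0 - s))
        return np.broadcast_to(val, z.shape).copy()

    def velocity(self, z, t):
        """Analytic time derivative of :meth:`displacement` (m/s)."""
        z = np.asarray(z, dtype=float)
        a = self.amplitude
        if self.kind == "heartbeat":
            phase = _TWO_PI * self.f * (t - (self.La - z) / self.c)
            return a * _TWO_PI * self.f * np.cos(phase)
        if self.kind == "sinusoid":
            val = a * _TWO_PI * self.f * math.cos(_TWO_PI * self.f * t)
            return np.broadcast_to(val, z.shape).copy()
        if t <= 0.0:
            return np.zeros(z.shape)
        s = float(t) / self.t_peak
        k = self.shape_k
        val = a * (k / self.t_peak) * s ** (k - 1.0) * (1.0 - s) * math.exp(k * (1.0 - s))
        return np.broadcast_to(val, z.shape).copy()


def heartbeat_displacement(z, t, params: ModelParameters, La: float | None = None):
    """Travelling-wave heartbeat displacement (m); see :class:`WallMotion`."""
    return WallMotion.heartbeat(params, La=La).displacement(z, t)


def hyperemia_displacement(t, params: ModelParameters):
    """Gamma-shaped functional-hyperemia dilation (m), uniform in z."""
    return float(WallMotion.hyperemia(params).displacement(0.0, t))


def sinusoid_displacement(t, f: float, params: ModelParameters):
    """Uniform 4% peak-to-peak sweep sinusoid displacement (m)."""
    return float(WallMotion.sinusoid(params, f).displacement(0.0, t))
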