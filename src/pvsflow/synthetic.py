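"""Synthetic two-photon movies with known ground truth.

Two generators exercise the image-analysis chain end to end without any
recorded data:

* :func:`generate_line_movie` - a random field of oriented lines (the
  texture of sparse YFP neurites) displaced uniformly radially outward
  with a gamma-function time course, plus additive noise at a target
  signal-to-noise ratio.  This is the displacement-pipeline validation
  design.
* :func:`generate_two_channel_movie` - a physics-informed two-channel
  recording: a red channel showing a dilating vessel lumen and a green
  line field displaced radially at a chosen tissue-to-wall ratio rho, with
  green-to-red crosstalk at a known coefficient and noise in both
  channels.  The "noncompliant" paradigm delays the tissue motion until
  the wall has closed the paravascular gap.

SNR follows the mean-signal / noise-standard-deviation convention (see
:func:`measure_snr`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from pvsflow.imaging import TwoChannelMovie, gamma_kernel

__all__ = ["SyntheticSpec", "generate_line_movie", "generate_two_channel_movie", "measure_snr",
           "render_line_field"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic movie generators.

    ``snr`` is mean signal / noise standard deviation.  ``amplitude_px`` is
    the peak radial displacement of the texture; the time course is a
    gamma function peaking at ``t_peak_s``.  For the two-channel generator
    ``tissue_ratio`` (rho) scales tissue motion relative to wall motion and
    ``paradigm`` selects the coupled (scaled-copy) or non-compliant
    (onset-delayed) tissue response.
    """

    shape: tuple[int, int] = (512, 512)
    n_lines: int = 100
    line_width_px: float = 2.5
    line_length_px: tuple[float, float] = (40.0, 120.0)
    n_frames: int = 40
    frame_rate: float = 3.0
    amplitude_px: float = 4.0
    t_peak_s: float = 1.5
    shape_k: float = 2.0
    onset_s: float = 2.0  # rest period before the event (reference frames)
    center: tuple[float, float] | None = None  # (row, col); default image centre
    vessel_radius_px: float = 24.0
    dilation_px: float = 6.0
    pvs_gap_px: float = 3.0
    crosstalk_alpha: float = 0.3
    tissue_ratio: float = 0.5
    paradigm: str = "coupled"  # or "noncompliant"
    snr: float = 4.14
    noise: str = "gaussian"  # or "poisson"
    seed: int = 0

    def __post_init__(self):
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.paradigm not in {"coupled", "noncompliant"}:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.center is None:
            self.center = (self.shape[0] / 2.0, self.shape[1] / 2.0)
        if self.vessel_radius_px + self.dilation_px > min(self.shape) / 2.0:
            raise ValueError("vessel does not fit in the frame")

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def displacement_trace(self) -> np.ndarray:
        """Ground-truth radial texture displacement per frame, px."""
        return gamma_kernel(self.times() - self.onset_s, self.amplitude_px,
                            self.t_peak_s, self.shape_k)

    def dilation_trace(self) -> np.ndarray:
        """Ground-truth vessel radius increase per frame, px."""
        return gamma_kernel(self.times() - self.onset_s, self.dilation_px,
                            self.t_peak_s, self.shape_k)

    def rest_frames(self) -> int:
        """Number of leading frames before the event onset."""
        return max(int(self.onset_s * self.frame_rate), 1)


def render_line_field(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Random field of smooth-profile line segments, intensities in [0, 1]."""
    H, W = spec.shape
    img = np.zeros((H, W))
    yy, xx = np.mgrid[0:H, 0:W]
    sigma = spec.line_width_px / 2.355  # FWHM -> gaussian sigma
    for _ in range(spec.n_lines):
        cx = rng.uniform(0, W)
        cy = rng.uniform(0, H)
        ang = rng.uniform(0, math.pi)
        L = rng.uniform(*spec.line_length_px)
        dx, dy = math.cos(ang), math.sin(ang)
        x0, y0 = cx - dx * L / 2, cy - dy * L / 2
        x1, y1 = cx + dx * L / 2, cy + dy * L / 2
        lo_r = max(int(min(y0, y1) - 4 * sigma), 0)
        hi_r = min(int(max(y0, y1) + 4 * sigma) + 1, H)
        lo_c = max(int(min(x0, x1) - 4 * sigma), 0)
        hi_c = min(int(max(x0, x1) + 4 * sigma) + 1, W)
        if lo_r >= hi_r or lo_c >= hi_c:
            continue
        X = xx[lo_r:hi_r, lo_c:hi_c]
        Y = yy[lo_r:hi_r, lo_c:hi_c]
        # distance from the segment
        tpar = ((X - x0) * dx + (Y - y0) * dy) / L
        tpar = np.clip(tpar, 0.0, 1.0)
        px = x0 + tpar * L * dx
        py = y0 + tpar * L * dy
        dist2 = (X - px) ** 2 + (Y - py) ** 2
        amp = rng.uniform(0.6, 1.0)
        img[lo_r:hi_r, lo_c:hi_c] = np.maximum(
            img[lo_r:hi_r, lo_c:hi_c], amp * np.exp(-dist2 / (2 * sigma**2)))
    return img


def _radial_warp(image: np.ndarray, center: tuple[float, float], disp: float) -> np.ndarray:
    """Displace the texture radially outward from ``center`` by ``disp``
    pixels (uniform magnitude), sampling with subpixel interpolation."""
    if disp == 0:
        return image.copy()
    H, W = image.shape
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    dy = yy - center[0]
    dx = xx - center[1]
    r = np.hypot(dy, dx)
    r_safe = np.where(r > 1e-9, r, 1.0)
    # inverse map: the pixel at radius r came from radius r - disp
    src_y = center[0] + dy / r_safe * np.maximum(r - disp, 0.0)
    src_x = center[1] + dx / r_safe * np.maximum(r - disp, 0.0)
    return ndimage.map_coordinates(image, [src_y, src_x], order=3, mode="reflect")


def _masks(base: np.ndarray, max_disp: float, threshold: float = 0.1):
    """Signal and background masks robust to the radial warp: the signal
    mask is dilated by the largest displacement so warped texture stays
    inside it; the background mask keeps a further safety margin."""
    core = base > threshold
    it_sig = max(int(np.ceil(max_disp)) + 1, 1)
    signal = ndimage.binary_dilation(core, iterations=it_sig)
    background = ~ndimage.binary_dilation(base > threshold / 5.0, iterations=it_sig + 3)
    return signal, background


def _add_noise(stack: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator,
               signal_mask: np.ndarray) -> np.ndarray:
    mean_signal = float(stack[..., signal_mask].mean()) if signal_mask.any() else float(stack.mean())
    sigma = mean_signal / spec.snr
    if spec.noise == "poisson":
        # scale so that the shot-noise std at the mean signal matches sigma
        lam = np.clip(stack, 0, None) * mean_signal / max(sigma**2, 1e-12)
        out = rng.poisson(lam).astype(float) * max(sigma**2, 1e-12) / mean_signal
        return out
    return stack + rng.normal(0.0, sigma, size=stack.shape)


def generate_line_movie(spec: SyntheticSpec):
    """Line-field movie with uniform radial displacement and noise.

    Returns (stack (frames, H, W), truth dict) where truth holds the clean
    base image, the per-frame radial displacement (px) and the signal mask
    used for SNR calibration.  Bit-identical for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    base = render_line_field(spec, rng)
    disp = spec.displacement_trace()
    clean = np.stack([_radial_warp(base, spec.center, d) for d in disp])
    signal_mask, background_mask = _masks(base, float(disp.max()))
    stack = _add_noise(clean, spec, rng, signal_mask)
    truth = {"base": base, "displacement_px": disp, "signal_mask": signal_mask,
             "background_mask": background_mask, "center": spec.center}
    return stack, truth


def _render_disk(shape, center, radius, edge_px: float = 1.0) -> np.ndarray:
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    r = np.hypot(yy - center[0], xx - center[1])
    return 1.0 / (1.0 + np.exp((r - radius) / max(edge_px / 4.0, 0.25)))


def generate_two_channel_movie(spec: SyntheticSpec):
    """Physics-informed two-channel movie plus ground truth.

    Red: a vessel lumen dilating by the gamma-shaped trace; green: the
    line field displaced radially by rho x wall displacement ("coupled"
    paradigm) or by rho x the excess of wall displacement over the PVS gap
    ("noncompliant": the tissue stays still until the gap has collapsed).
    Crosstalk adds alpha x green into red; both channels receive noise at
    the target SNR.
    """
    rng = np.random.default_rng(spec.seed)
    base = render_line_field(spec, rng)
    # no neurites inside the vessel lumen: carve out the maximally dilated
    # disk (plus margin) so red and green content stay spatially disjoint
    lumen = _render_disk(spec.shape, spec.center,
                         spec.vessel_radius_px + spec.dilation_px + 2.0)
    base = base * (1.0 - (lumen > 0.5))
    dil = spec.dilation_trace()
    if spec.paradigm == "coupled":
        tissue = spec.tissue_ratio * dil
    else:
        tissue = spec.tissue_ratio * np.clip(dil - spec.pvs_gap_px, 0.0, None)
    red_clean = np.stack([
        _render_disk(spec.shape, spec.center, spec.vessel_radius_px + d) for d in dil])
    green_clean = np.stack([_radial_warp(base, spec.center, d) for d in tissue])
    red_mix = red_clean + spec.crosstalk_alpha * green_clean

    mask_g, bg_g = _masks(base, float(tissue.max()))
    mask_r = red_clean[0] > 0.5
    red = _add_noise(red_mix, spec, rng, mask_r)
    green = _add_noise(green_clean, spec, rng, mask_g)
    movie = TwoChannelMovie(red=red, green=green, frame_rate=spec.frame_rate,
                            vessel_center=spec.center)
    truth = {
        "dilation_px": dil,
        "tissue_px": tissue,
        "base": base,
        "alpha": spec.crosstalk_alpha,
        "tissue_ratio": spec.tissue_ratio,
        "center": spec.center,
        "red_clean": red_clean,
        "green_clean": green_clean,
        "signal_mask": mask_g,
        "background_mask": bg_g,
    }
    return movie, truth


def measure_snr(stack: np.ndarray, signal_mask: np.ndarray,
                background_mask: np.ndarray | None = None) -> float:
    """Mean signal value divided by the noise standard deviation.

    The noise spread is estimated from background pixels (by default the
    complement of ``signal_mask``); for a noiseless stack the background
    is constant and the ratio is infinite (returned as ``inf``).
    """
    signal_mask = np.asarray(signal_mask, dtype=bool)
    if not signal_mask.any():
        raise ValueError("empty signal mask")
    if background_mask is None:
        background_mask = ~signal_mask
    stack = np.asarray(stack, dtype=float)
    mean_signal = float(stack[..., signal_mask].mean()) if stack.ndim == 3 \
        else float(stack[signal_mask].mean())
    bg = stack[..., background_mask] if stack.ndim == 3 else stack[background_mask]
    noise_sd = float(bg.std())
    if noise_sd == 0:
        return math.inf
    return mean_signal / noise_sd
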