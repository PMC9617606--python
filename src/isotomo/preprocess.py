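"""CTF Wiener deconvolution and statistical mask generation.

Deconvolution model
-------------------
Tomograms acquired at underfocus without a phase plate carry the oscillatory
contrast transfer function (CTF).  A Wiener filter

    W(f) = CTF(f) / (CTF(f)^2 + 1/SSNR(f))

is applied as a rotationally symmetric 3D filter, with the spectral
signal-to-noise ratio set empirically:

    SSNR(f) = exp(-f * 100 * F) * 10^S * H(f)

where ``F`` is the fall-off parameter, ``S`` the strength parameter, ``f``
the spatial frequency in cycles/pixel and ``H`` a high-pass filter.  ``H`` is
a cosine ramp, zero at DC and one beyond ``highpass_freq``:

    H(f) = (1 - cos(pi * min(f / f_hp, 1))) / 2

A single defocus per tomogram is assumed (the volume is already
reconstructed; no depth gradient).  Underfocus is positive and produces
negative low-frequency contrast.  The DC coefficient is left unchanged so the
volume mean survives deconvolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .tomio import Tomogram

__all__ = [
    "DeconvParams",
    "MaskParams",
    "ssnr",
    "ctf_1d",
    "wiener_gain",
    "deconvolve",
    "density_mask",
    "std_mask",
    "make_mask",
]


@dataclass
class DeconvParams:
    """Parameters of the empirical SSNR model and the microscope CTF.

    snrfalloff : dimensionless fall-off F (>= 0); larger = faster SSNR decay
    strength : dimensionless strength S; SSNR scales as 10**S
    highpass_freq : cosine-ramp high-pass corner, cycles/pixel
    defocus : micrometres, underfocus positive
    voltage : accelerating voltage, kV
    cs : spherical aberration, mm
    amplitude_contrast : fraction in [0, 1]
    pixel_size : Angstrom per voxel
    """

    snrfalloff: float = 1.0
    strength: float = 1.0
    highpass_freq: float = 0.02
    defocus: float = 4.0
    voltage: float = 300.0
    cs: float = 2.7
    amplitude_contrast: float = 0.07
    pixel_size: float = 10.0

    def __post_init__(self):
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude_contrast must be in [0, 1]")


@dataclass
class MaskParams:
    """Parameters of the empty-region mask.

    density_percentage / std_percentage : percentage of voxels kept by the
        density and local-standard-deviation criteria, in (0, 100]
    gaussian_sigma : pre-smoothing sigma, voxels
    max_window / std_window : odd cubic window edges, voxels
    z_crop : fraction of slices zeroed at each of the top and bottom in Z
    """

    density_percentage: float = 50.0
    std_percentage: float = 50.0
    gaussian_sigma: float = 2.0
    max_window: int = 5
    std_window: int = 5
    z_crop: float = 0.0

    def __post_init__(self):
        for name in ("density_percentage", "std_percentage"):
            v = getattr(self, name)
            if not 0.0 < v <= 100.0:
                raise ValueError(f"{name} must be in (0, 100], got {v}")
        for name in ("max_window", "std_window"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 1, got {v}")
        if not 0.0 <= self.z_crop < 0.5:
            raise ValueError(f"z_crop must be in [0, 0.5), got {self.z_crop}")


def _highpass(f, f_hp):
    x = np.minimum(np.asarray(f, dtype=float) / f_hp, 1.0)
    return (1.0 - np.cos(np.pi * x)) / 2.0


def ssnr(f, params: DeconvParams):
    """Empirical spectral SNR at frequency ``f`` (cycles/pixel)."""
    f = np.asarray(f, dtype=float)
    if (f < 0).any():
        raise ValueError("spatial frequency must be non-negative")
    return (np.exp(-f * 100.0 * params.snrfalloff)
            * 10.0 ** params.strength
            * _highpass(f, params.highpass_freq))


def _wavelength_A(voltage_kV: float) -> float:
    """Relativistic electron wavelength in Angstrom."""
    v = voltage_kV * 1e3
    return 12.2639 / np.sqrt(v * (1.0 + v * 0.97845e-6))


def ctf_1d(f, params: DeconvParams):
    """1D CTF at frequency ``f`` in cycles/pixel; value in [-1, 1].

    CTF(f) = -( sqrt(1 - A^2) sin chi + A cos chi ),
    chi = pi lambda dz f^2 - (pi/2) Cs lambda^3 f^4     (f in 1/Angstrom).
    """
    f = np.asarray(f, dtype=float)
    fa = f / params.pixel_size
    lam = _wavelength_A(params.voltage)
    dz = params.defocus * 1e4          # um -> A
    cs = params.cs * 1e7               # mm -> A
    chi = np.pi * lam * dz * fa ** 2 - 0.5 * np.pi * cs * lam ** 3 * fa ** 4
    a = params.amplitude_contrast
    return -(np.sqrt(1.0 - a * a) * np.sin(chi) + a * np.cos(chi))


def wiener_gain(f, params: DeconvParams):
    """Radial Wiener gain W(f) = CTF/(CTF^2 + 1/SSNR); zero where SSNR = 0."""
    f = np.asarray(f, dtype=float)
    s = ssnr(f, params)
    c = ctf_1d(f, params)
    w = np.zeros_like(c)
    pos = s > 0
    w[pos] = c[pos] / (c[pos] ** 2 + 1.0 / s[pos])
    return w


def deconvolve(vol: Tomogram, params: DeconvParams) -> Tomogram:
    """Apply the radial 3D Wiener deconvolution filter to a tomogram."""
    data = np.asarray(vol.data, dtype=np.float32)
    freqs = [np.fft.fftfreq(n) for n in data.shape]
    kz, ky, kx = np.meshgrid(*freqs, indexing="ij", sparse=True)
    f = np.sqrt(kz ** 2 + ky ** 2 + kx ** 2)
    w = wiener_gain(f.ravel(), params).reshape(f.shape)
    if not (w != 0).any():
        raise ValueError("degenerate deconvolution parameters: SSNR is zero everywhere")
    w[0, 0, 0] = 1.0  # keep the measured mean
    out = np.fft.ifftn(np.fft.fftn(data) * w).real.astype(np.float32)
    return vol.with_data(out, suffix="_deconv")


def _keep_top_percent(score: np.ndarray, percentage: float) -> np.ndarray:
    """Boolean mask of the top `percentage`% scores; strict > at the threshold."""
    if percentage >= 100.0:
        return np.ones(score.shape, dtype=bool)
    thr = np.percentile(score, 100.0 - percentage)
    return score > thr


def density_mask(vol: Tomogram, p: MaskParams) -> np.ndarray:
    """Keep high-density regions of the contrast-inverted, smoothed tomogram."""
    inverted = -np.asarray(vol.data, dtype=np.float32)
    smoothed = ndimage.gaussian_filter(inverted, p.gaussian_sigma)
    filtered = ndimage.maximum_filter(smoothed, size=p.max_window)
    return _keep_top_percent(filtered, p.density_percentage)


def std_mask(vol: Tomogram, p: MaskParams) -> np.ndarray:
    """Keep regions whose local standard deviation is in the top percentage."""
    data = np.asarray(vol.data, dtype=np.float64)
    mean = ndimage.uniform_filter(data, size=p.std_window)
    meansq = ndimage.uniform_filter(data ** 2, size=p.std_window)
    local_std = np.sqrt(np.maximum(meansq - mean ** 2, 0.0))
    mask = _keep_top_percent(local_std, p.std_percentage)
    if not mask.any():
        warnings.warn("standard-deviation mask is empty (constant volume?)")
    return mask


def make_mask(vol: Tomogram, p: MaskParams) -> np.ndarray:
    """Intersection of the density and std masks, with top/bottom Z slices cut."""
    mask = density_mask(vol, p) & std_mask(vol, p)
    nz = mask.shape[0]
    ncrop = int(round(nz * p.z_crop))
    if ncrop > 0:
        mask[:ncrop] = False
        mask[nz - ncrop:] = False
    return mask
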