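"""Reconstruction-consistent noise simulation and the step-wise denoise schedule.

Noise in a tomogram is not white: each tilt image contributes (approximately
Gaussian) noise that the reconstruction smears along its beam direction, so
the 3D noise power lives inside the sampled Fourier fan.  We emulate this by
backprojecting independent 2D Gaussian noise images over the tilt range:
replicate each (optionally ramp- or Hamming-ramp-filtered) image along Z and
rotate the slab about the Y axis by its tilt angle, accumulating the results.

The three filter kinds mirror the common reconstruction flavours: plain
backprojection (SIRT-like spectra), ramp-filtered (weighted backprojection),
and a Hamming-windowed ramp.

The denoising module is a noisier-input strategy: scaled noise volumes are
added to the *input* member of each training pair only, the target stays
clean, and the noise level follows a warmup-then-staircase schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "NoiseConfig",
    "ScheduleConfig",
    "backproject_noise",
    "add_noise",
    "denoise_schedule",
]


def _default_angles():
    return list(np.arange(-60.0, 60.0 + 1e-9, 2.0))


@dataclass
class NoiseConfig:
    """filter_kind: 'none' | 'ramp' | 'hamming'; tilt_angles in degrees."""

    filter_kind: str = "none"
    tilt_angles: list = field(default_factory=_default_angles)

    def __post_init__(self):
        if self.filter_kind not in ("none", "ramp", "hamming"):
            raise ValueError(f"unknown filter kind {self.filter_kind!r}")
        if any(not -90 < a < 90 for a in self.tilt_angles):
            raise ValueError("tilt angles must lie in (-90, 90)")
        if len(self.tilt_angles) == 0:
            raise ValueError("empty tilt angle list")


@dataclass
class ScheduleConfig:
    """Warmup-then-staircase denoise schedule.

    Level is 0 for the first `warmup_iters` iterations, then rises by `step`
    every `step_every` iterations up to `max_level`.  Defaults: ten warmup
    iterations, +0.05 every five iterations, capped at 0.2.
    """

    warmup_iters: int = 10
    step: float = 0.05
    step_every: int = 5
    max_level: float = 0.2

    def __post_init__(self):
        if min(self.warmup_iters, self.step, self.step_every, self.max_level) < 0:
            raise ValueError("schedule parameters must be non-negative")


def _filter_1d(n: int, kind: str) -> np.ndarray:
    """Frequency weights applied along the tilt-perpendicular image axis."""
    f = np.abs(np.fft.fftfreq(n))
    if kind == "ramp":
        return f
    if kind == "hamming":
        # ramp multiplied by a Hamming window reaching its minimum at Nyquist
        return f * (0.54 + 0.46 * np.cos(np.pi * f / 0.5))
    return np.ones_like(f)


def backproject_noise(shape: int, cfg: NoiseConfig, rng_seed: int) -> np.ndarray:
    """A zero-mean, unit-std noise cube with tomographic spectral structure.

    For each tilt angle an independent iid Gaussian image (axes y, x) is
    drawn, filtered along x, replicated along Z, rotated about Y by the tilt
    angle (trilinear interpolation), and accumulated.
    """
    n = int(shape)
    rng = np.random.default_rng(rng_seed)
    filt = _filter_1d(n, cfg.filter_kind)
    acc = np.zeros((n, n, n), dtype=np.float32)
    for angle in cfg.tilt_angles:
        img = rng.standard_normal((n, n))
        if cfg.filter_kind != "none":
            img = np.fft.ifft(np.fft.fft(img, axis=1) * filt[None, :], axis=1).real
        slab = np.broadcast_to(img[None, :, :].astype(np.float32), (n, n, n))
        acc += ndimage.rotate(slab, angle, axes=(0, 2), reshape=False,
                              order=1, mode="constant", cval=0.0)
    acc -= acc.mean()
    std = acc.std()
    if std == 0:
        raise ValueError("degenerate noise volume")
    return (acc / std).astype(np.float32)


def add_noise(input_cube: np.ndarray, noise: np.ndarray, level: float) -> np.ndarray:
    """Add noise scaled so std(added)/std(input) equals `level`.

    The target member of a training pair is never touched; only the input is
    made noisier.
    """
    input_cube = np.asarray(input_cube)
    if input_cube.shape != np.shape(noise):
        raise ValueError("input and noise shapes differ")
    if level == 0:
        return input_cube
    s_in = float(np.std(input_cube))
    s_no = float(np.std(noise))
    if s_in == 0:
        raise ValueError("zero-std input cube")
    if s_no == 0:
        raise ValueError("zero-std noise volume")
    return (input_cube + noise * (level * s_in / s_no)).astype(input_cube.dtype)


def denoise_schedule(iteration: int, cfg: ScheduleConfig = ScheduleConfig()) -> float:
    """Denoise level (std ratio) at a 1-based refinement iteration."""
    if iteration < 1:
        raise ValueError("iteration is 1-based")
    if iteration <= cfg.warmup_iters:
        return 0.0
    blocks = int(np.ceil((iteration - cfg.warmup_iters) / cfg.step_every))
    return float(min(cfg.max_level, cfg.step * blocks))
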