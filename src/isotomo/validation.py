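"""Fourier shell correlation: global, conical (directional), and 3D.

The gold-standard protocol compares two reconstructions obtained from
independently processed halves of the data; the frequency at which their
shell correlation drops below 0.5 or 0.143 is reported as the resolution.
Conical FSC restricts each shell to a double cone of Fourier directions and
so measures resolution anisotropy, e.g. the Z-direction degradation left by
an incompletely restored wedge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FscCurve",
    "Fsc3D",
    "fsc",
    "conical_fsc",
    "resolution_at",
    "gold_standard_3dfsc",
    "fibonacci_directions",
]


@dataclass
class FscCurve:
    """Shell correlations; frequencies in cycles/pixel (DC shell excluded)."""

    freq: np.ndarray
    values: np.ndarray
    pixel_size: float = 1.0

    def __len__(self):
        return len(self.freq)


@dataclass
class Fsc3D:
    """Cone-aggregated directional FSC on a grid of directions."""

    directions: np.ndarray          # (K, 3) unit vectors, (x, y, z) components
    curves: np.ndarray              # (K, n_shells)
    freq: np.ndarray                # shared shell frequencies, cycles/pixel
    pixel_size: float = 1.0
    half_angle: float = 20.0

    def resolution_map(self, cutoff: float = 0.143) -> np.ndarray:
        """Per-direction resolution (Angstrom) at the given cutoff."""
        return np.array([
            resolution_at(FscCurve(self.freq, c, self.pixel_size), cutoff)[0]
            for c in self.curves
        ])


def _shell_index(shape):
    """Integer shell number per Fourier voxel plus frequency axes."""
    grids = [np.fft.fftfreq(n) for n in shape]
    kz, ky, kx = np.meshgrid(*grids, indexing="ij", sparse=True)
    r = np.sqrt(kz ** 2 + ky ** 2 + kx ** 2)
    n = min(shape)
    shell = np.rint(r * n).astype(int)
    return shell, (kz, ky, kx), n


def _fsc_from_masks(fa, fb, shell, n_shells, select=None):
    """Per-shell normalized cross-correlation, optionally voxel-masked."""
    num = (fa * np.conj(fb)).real
    pa = np.abs(fa) ** 2
    pb = np.abs(fb) ** 2
    if select is not None:
        w = select.astype(float)
        num, pa, pb = num * w, pa * w, pb * w
    sums_n = np.bincount(shell.ravel(), num.ravel(), minlength=n_shells)
    sums_a = np.bincount(shell.ravel(), pa.ravel(), minlength=n_shells)
    sums_b = np.bincount(shell.ravel(), pb.ravel(), minlength=n_shells)
    denom = np.sqrt(sums_a * sums_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, sums_n / denom, np.nan)
    return vals


def fsc(a: np.ndarray, b: np.ndarray, pixel_size: float = 1.0) -> FscCurve:
    """Global Fourier shell correlation of two same-shape volumes."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("volume shapes differ")
    shell, _, n = _shell_index(a.shape)
    fa, fb = np.fft.fftn(a), np.fft.fftn(b)
    n_shells = n // 2 + 1
    inside = shell < n_shells
    vals = _fsc_from_masks(fa, fb, np.where(inside, shell, 0), n_shells,
                           select=inside)
    freq = np.arange(1, n_shells) / n
    return FscCurve(freq, vals[1:], pixel_size)


def conical_fsc(a, b, direction, half_angle: float = 20.0,
                pixel_size: float = 1.0) -> FscCurve:
    """FSC restricted to the double cone of `half_angle` about `direction`.

    `direction` is an (x, y, z) unit vector.  Shells with no voxels in the
    cone are reported as NaN.
    """
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("volume shapes differ")
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    shell, (kz, ky, kx), n = _shell_index(a.shape)
    r = np.sqrt(kz ** 2 + ky ** 2 + kx ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.abs(kx * d[0] + ky * d[1] + kz * d[2]) / np.where(r > 0, r, 1.0)
    in_cone = cosang >= np.cos(np.radians(half_angle))
    in_cone = in_cone | (r == 0)
    n_shells = n // 2 + 1
    inside = (shell < n_shells) & in_cone
    fa, fb = np.fft.fftn(a), np.fft.fftn(b)
    vals = _fsc_from_masks(fa, fb, np.where(inside, shell, 0), n_shells,
                           select=inside)
    freq = np.arange(1, n_shells) / n
    return FscCurve(freq, vals[1:], pixel_size)


def resolution_at(curve: FscCurve, cutoff: float = 0.143):
    """Resolution (Angstrom) at the first downward crossing of `cutoff`.

    Linear interpolation between shells.  Returns ``(resolution, flag)``;
    flag is 'nyquist' when the curve never drops below the cutoff and
    'below_cutoff' when even the lowest-frequency shell is already under it.
    """
    v = np.asarray(curve.values, dtype=float)
    f = np.asarray(curve.freq, dtype=float)
    ok = np.isfinite(v)
    v, f = v[ok], f[ok]
    if len(v) < 2:
        raise ValueError("need at least two finite shells")
    if v[0] < cutoff:
        return float(curve.pixel_size / f[0]), "below_cutoff"
    for i in range(1, len(v)):
        if v[i] < cutoff:
            frac = (v[i - 1] - cutoff) / (v[i - 1] - v[i])
            fc = f[i - 1] + frac * (f[i] - f[i - 1])
            return float(curve.pixel_size / fc), "crossed"
    return float(2.0 * curve.pixel_size), "nyquist"


def fibonacci_directions(k: int) -> np.ndarray:
    """k approximately uniform directions on the upper hemisphere."""
    i = np.arange(k)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = (i + 0.5) / k
    r = np.sqrt(1.0 - z ** 2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def threed_fsc(a, b, n_directions: int = 49, half_angle: float = 20.0,
               pixel_size: float = 1.0) -> Fsc3D:
    """Conical FSC over a hemisphere grid of directions."""
    dirs = fibonacci_directions(n_directions)
    curves = [conical_fsc(a, b, d, half_angle, pixel_size).values for d in dirs]
    n = min(np.shape(a))
    freq = np.arange(1, n // 2 + 1) / n
    return Fsc3D(dirs, np.asarray(curves), freq, pixel_size, half_angle)


def gold_standard_3dfsc(half1: np.ndarray, half2: np.ndarray, n_cubes: int = 4,
                        cube: int = 64, n_directions: int = 49,
                        half_angle: float = 20.0,
                        pixel_size: float = 1.0) -> Fsc3D:
    """Average the 3D FSC of matched cubes cropped from two half-maps.

    Cube positions are drawn reproducibly and are identical in both volumes;
    the half-maps come from independently trained networks, so their
    agreement is a gold-standard resolution measure.
    """
    half1, half2 = np.asarray(half1), np.asarray(half2)
    if half1.shape != half2.shape:
        raise ValueError("half-map shapes differ")
    if min(half1.shape) < cube:
        raise ValueError(f"volumes {half1.shape} too small for cube {cube}")
    rng = np.random.default_rng(0)
    positions = []
    for _ in range(n_cubes):
        positions.append(tuple(
            int(v) for v in rng.integers(0, np.array(half1.shape) - cube + 1)))
    acc = None
    for pos in positions:
        sl = tuple(slice(p, p + cube) for p in pos)
        f3 = threed_fsc(half1[sl], half2[sl], n_directions, half_angle, pixel_size)
        acc = f3 if acc is None else Fsc3D(
            f3.directions, acc.curves + f3.curves, f3.freq, pixel_size, half_angle)
    return Fsc3D(acc.directions, acc.curves / n_cubes, acc.freq, pixel_size,
                 half_angle)
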