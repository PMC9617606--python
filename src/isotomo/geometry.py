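"""Missing-wedge Fourier filters, the cubic rotation group, and information merging.

Single-axis tomography with tilt axis Y and a limited tilt range leaves a
double-wedge region of Fourier space unsampled.  Everything in this module is
expressed on the discrete Fourier grid in the ``numpy.fft`` (unshifted) layout;
volumes are real arrays indexed ``(z, y, x)``.

The wedge convention: a tilt at angle ``a`` (degrees, about Y) measures the
central plane of Fourier space whose in-plane direction in the (kx, kz) plane
makes angle ``a`` with the kx axis.  A Fourier voxel is *sampled* iff the
signed angle of its (kx, kz) direction (reduced to the Hermitian
representative in (-90, 90]) lies within ``[tilt_min, tilt_max]`` inclusive;
ky is unconstrained.  The DC voxel is always sampled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WedgeSpec",
    "Rotation",
    "FourierFilter",
    "wedge_filter",
    "inverse_wedge_filter",
    "apply_fourier_filter",
    "cube_rotations",
    "training_rotations",
    "rotate_volume",
    "fourier_merge",
]


@dataclass(frozen=True)
class WedgeSpec:
    """Tilt-range description of the missing wedge (degrees, tilt axis Y)."""

    tilt_min: float = -60.0
    tilt_max: float = 60.0

    def __post_init__(self):
        if not (-90.0 < self.tilt_min < self.tilt_max < 90.0):
            raise ValueError(
                f"require -90 < tilt_min < tilt_max < 90, got "
                f"[{self.tilt_min}, {self.tilt_max}]"
            )


@dataclass(frozen=True)
class Rotation:
    """A proper rotation of the cube: a signed permutation matrix with det +1."""

    matrix: np.ndarray
    label: str = ""

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=int)
        object.__setattr__(self, "matrix", m)
        if m.shape != (3, 3) or not np.isin(m, (-1, 0, 1)).all():
            raise ValueError("rotation must be a 3x3 signed permutation matrix")
        if (np.abs(m).sum(axis=0) != 1).any() or (np.abs(m).sum(axis=1) != 1).any():
            raise ValueError("exactly one nonzero entry per row and column required")
        if round(np.linalg.det(m)) != 1:
            raise ValueError("determinant must be +1 (proper rotation)")

    def __matmul__(self, other: "Rotation") -> "Rotation":
        return Rotation(self.matrix @ other.matrix, f"{self.label}*{other.label}")

    @property
    def inverse(self) -> "Rotation":
        return Rotation(self.matrix.T, f"inv({self.label})")

    def __eq__(self, other):
        return isinstance(other, Rotation) and (self.matrix == other.matrix).all()

    def __hash__(self):
        return hash(self.matrix.tobytes())


@dataclass
class FourierFilter:
    """Real non-negative weights on the (unshifted) discrete Fourier grid."""

    data: np.ndarray
    shape: tuple = field(init=False)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.shape = self.data.shape


def _plane_angle_deg(kx, kz):
    """Signed angle (deg) of the (kx, kz) direction, Hermitian representative.

    Each Fourier voxel and its Hermitian mate (-k) carry the same information;
    we reduce to the half-space kx >= 0 so the angle lies in [-90, 90].
    """
    kx = np.asarray(kx, dtype=float)
    kz = np.asarray(kz, dtype=float)
    flip = kx < 0
    kx = np.where(flip, -kx, kx)
    kz = np.where(flip, -kz, kz)
    ang = np.degrees(np.arctan2(kz, kx))
    # kx == 0, kz < 0 maps to -90; fold onto +90 (same line through origin)
    return np.where(ang == -90.0, 90.0, ang)


def _sampled_region(shape, w: WedgeSpec) -> np.ndarray:
    """Boolean grid, True where Fourier space is measured by the tilt fan."""
    nz, ny, nx = shape
    kzv = np.fft.fftfreq(nz)[:, None, None]
    kxv = np.fft.fftfreq(nx)[None, None, :]
    ang = _plane_angle_deg(np.broadcast_to(kxv, (nz, 1, nx)),
                           np.broadcast_to(kzv, (nz, 1, nx)))
    sampled = (ang >= w.tilt_min) & (ang <= w.tilt_max)
    sampled[0, 0, 0] = True  # DC is measured data
    return np.broadcast_to(sampled, (nz, ny, nx)).copy()


def wedge_filter(shape, w: WedgeSpec = WedgeSpec()) -> FourierFilter:
    """Binary filter: 1 on the sampled region, 0 inside the missing wedge."""
    return FourierFilter(_sampled_region(shape, w).astype(np.float32))


def inverse_wedge_filter(shape, w: WedgeSpec = WedgeSpec()) -> FourierFilter:
    """Complement filter: 1 inside the missing wedge, 0 elsewhere (DC = 0)."""
    s = _sampled_region(shape, w)
    inv = (~s).astype(np.float32)
    inv[0, 0, 0] = 0.0
    return FourierFilter(inv)


def apply_fourier_filter(vol: np.ndarray, filt: FourierFilter) -> np.ndarray:
    """Multiply the volume's Fourier transform by the filter, return real part."""
    vol = np.asarray(vol)
    if vol.shape != filt.shape:
        raise ValueError(f"shape mismatch: volume {vol.shape} vs filter {filt.shape}")
    out = np.fft.ifftn(np.fft.fftn(vol) * filt.data).real
    return out.astype(vol.dtype, copy=False)


def _axis_angle_label(m: np.ndarray) -> str:
    tr = int(np.trace(m))
    if tr == 3:
        return "identity"
    angle = {1: 90, 0: 120, -1: 180}[tr]
    # rotation axis: eigenvector for eigenvalue +1 (integer arithmetic)
    a = np.array([m[2, 1] - m[1, 2], m[0, 2] - m[2, 0], m[1, 0] - m[0, 1]])
    if not a.any():  # 180 degrees: axis from (M + I) columns
        b = m + np.eye(3, dtype=int)
        a = b[:, np.argmax((b != 0).any(axis=0))]
    g = np.gcd.reduce(np.abs(a[a != 0]))
    a = a // g
    return f"{angle}deg@[{a[0]},{a[1]},{a[2]}]"


def cube_rotations() -> list[Rotation]:
    """The 24 proper rotations of a cube as signed permutation matrices."""
    rots = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            m = np.zeros((3, 3), dtype=int)
            for row, (col, s) in enumerate(zip(perm, signs)):
                m[row, col] = s
            if round(np.linalg.det(m)) == 1:
                rots.append(Rotation(m, _axis_angle_label(m)))
    assert len(rots) == 24
    return rots


def _preserves_wedge(r: Rotation, w: WedgeSpec, n: int = 17) -> bool:
    """Does the rotation map the missing-wedge region onto itself?

    Checked exactly on a centered odd integer frequency grid, which every
    signed permutation maps onto itself.
    """
    half = n // 2
    c = np.arange(-half, half + 1)
    kz, ky, kx = np.meshgrid(c, c, c, indexing="ij")
    ang = _plane_angle_deg(kx, kz)
    sampled = (ang >= w.tilt_min) & (ang <= w.tilt_max)
    sampled[half, half, half] = True
    # rotated coordinates (xyz convention)
    m = r.matrix
    kxr = m[0, 0] * kx + m[0, 1] * ky + m[0, 2] * kz
    kzr = m[2, 0] * kx + m[2, 1] * ky + m[2, 2] * kz
    angr = _plane_angle_deg(kxr, kzr)
    sampled_r = (angr >= w.tilt_min) & (angr <= w.tilt_max)
    sampled_r[half, half, half] = True
    return bool((sampled == sampled_r).all())


def training_rotations(w: WedgeSpec = WedgeSpec()) -> list[Rotation]:
    """Rotations that move the missing wedge to a new direction.

    Of the 24 cube rotations, those mapping the wedge region onto itself are
    useless as augmentations (the re-imposed wedge would coincide with the
    original); for a symmetric Y-axis wedge exactly 4 are excluded, leaving 20.
    """
    return [r for r in cube_rotations() if not _preserves_wedge(r, w)]


def rotate_volume(vol: np.ndarray, r: Rotation) -> np.ndarray:
    """Exact (lossless) rotation of a cubic volume by a cube-group element.

    Pure axis permutation plus flips; no interpolation.  Input is indexed
    (z, y, x) while rotation matrices act on (x, y, z) vectors.
    """
    vol = np.asarray(vol)
    if vol.ndim != 3:
        raise ValueError("expected a 3D volume")
    m = r.matrix
    # output xyz-axis a_out draws from input xyz-axis a_in with sign s
    perm = [0, 0, 0]
    sign = [1, 1, 1]
    for a_out in range(3):
        a_in = int(np.flatnonzero(m[a_out])[0])
        perm[a_out] = a_in
        sign[a_out] = int(m[a_out, a_in])
    if perm != [0, 1, 2] and len(set(vol.shape)) != 1:
        raise ValueError("non-cubic volume only admits axis-preserving rotations")
    # numpy axis for xyz-axis a is (2 - a); output arr axes ordered (z, y, x)
    out = np.transpose(vol, axes=[2 - perm[2], 2 - perm[1], 2 - perm[0]])
    flips = [axis for axis, a_xyz in enumerate((2, 1, 0)) if sign[a_xyz] < 0]
    if flips:
        out = np.flip(out, axis=flips)
    return np.ascontiguousarray(out)


def fourier_merge(original: np.ndarray, predicted: np.ndarray,
                  w: WedgeSpec = WedgeSpec()) -> np.ndarray:
    """Take the wedge region of `predicted` and everything else from `original`.

    The sampled Fourier region of the output equals the original's exactly (up
    to FFT round-off): measured data is never modified, only the unmeasured
    wedge is filled from the network prediction.
    """
    original = np.asarray(original)
    if original.shape != np.shape(predicted):
        raise ValueError("shape mismatch between original and predicted volumes")
    inv = inverse_wedge_filter(original.shape, w)
    fill = np.fft.ifftn(np.fft.fftn(predicted) * inv.data).real
    return (original + fill).astype(original.dtype, copy=False)
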