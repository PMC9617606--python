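"""Subtomogram extraction, percentile normalization, and training-pair generation.

Training pairs implement the self-supervised scheme: the *target* is a
subtomogram rotated by a cube-group element that moves its missing wedge to a
new direction; the *input* is the same rotated volume with the standard wedge
re-imposed in Fourier space.  The network therefore learns to undo exactly
one wedge's worth of information loss.  Both members are centre-cropped
*after* filtering so edge voxels carry complete Fourier information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .geometry import Rotation, WedgeSpec
from .tomio import Tomogram

__all__ = [
    "NormTransform",
    "SubTomogramSet",
    "TrainingPair",
    "sample_seeds",
    "normalize_percentile",
    "extract",
    "center_crop",
    "make_training_pair",
    "build_epoch_dataset",
]


@dataclass(frozen=True)
class NormTransform:
    """The affine map v -> (v - offset) / scale recorded during normalization."""

    offset: float
    scale: float

    def apply(self, v):
        return (np.asarray(v) - self.offset) / self.scale

    def invert(self, v):
        return np.asarray(v) * self.scale + self.offset


@dataclass
class SubTomogramSet:
    """Extracted cubes with their provenance.

    cubes : (n, c, c, c) float32 array
    seeds : (n, 3) integer voxel coordinates (z, y, x) of cube centres
    source : name of the source tomogram
    half_id : (n,) int array of 0/1 half assignments, or None if unsplit
    norm_transforms : per-cube affine transforms applied during normalization
    """

    cubes: np.ndarray
    seeds: np.ndarray
    source: str = ""
    half_id: np.ndarray | None = None
    norm_transforms: list = field(default_factory=list)

    def __post_init__(self):
        self.cubes = np.asarray(self.cubes, dtype=np.float32)
        if self.cubes.ndim != 4:
            raise ValueError("cubes must be a (n, c, c, c) array")

    def __len__(self):
        return len(self.cubes)

    @property
    def cube_size(self):
        return self.cubes.shape[1]

    def half(self, which: int) -> "SubTomogramSet":
        if self.half_id is None:
            raise ValueError("set was extracted without split=True")
        idx = np.flatnonzero(self.half_id == which)
        return SubTomogramSet(
            self.cubes[idx], self.seeds[idx], self.source,
            np.full(len(idx), which),
            [self.norm_transforms[i] for i in idx] if self.norm_transforms else [],
        )


@dataclass
class TrainingPair:
    """(input, target) cube pair for one rotation of one subtomogram."""

    input: np.ndarray
    target: np.ndarray
    rotation: Rotation
    source_index: int = -1


def sample_seeds(mask: np.ndarray, count: int, cube_size: int,
                 rng_seed: int) -> np.ndarray:
    """Draw `count` distinct seed coordinates uniformly from the eligible mask.

    A voxel is eligible if it is True in the mask and a cube of `cube_size`
    centred on it fits inside the volume.
    """
    mask = np.asarray(mask, dtype=bool)
    m = cube_size // 2
    eligible = np.zeros_like(mask)
    hi = [n - cube_size + m + 1 for n in mask.shape]
    if any(h <= m for h in hi):
        raise ValueError(f"cube_size {cube_size} does not fit in volume {mask.shape}")
    eligible[m:hi[0], m:hi[1], m:hi[2]] = mask[m:hi[0], m:hi[1], m:hi[2]]
    flat = np.flatnonzero(eligible)
    if len(flat) < count:
        raise ValueError(
            f"only {len(flat)} eligible voxels for {count} requested seeds "
            f"(short by {count - len(flat)})"
        )
    rng = np.random.default_rng(rng_seed)
    chosen = rng.choice(flat, size=count, replace=False)
    return np.stack(np.unravel_index(chosen, mask.shape), axis=1)


def normalize_percentile(vol: np.ndarray, lo: float = 5.0, hi: float = 95.0):
    """Map the `lo` percentile to 0 and the `hi` percentile to 1.

    With the default symmetric (5, 95) pair, 90% of voxel values land inside
    (0, 1).  Returns ``(normalized, NormTransform)``.
    """
    vol = np.asarray(vol, dtype=np.float32)
    p_lo, p_hi = np.percentile(vol, [lo, hi])
    scale = float(p_hi - p_lo)
    if scale <= 0:
        raise ValueError("degenerate input: percentile range collapsed (constant volume?)")
    t = NormTransform(offset=float(p_lo), scale=scale)
    return t.apply(vol).astype(np.float32), t


def center_crop(vol: np.ndarray, size: int) -> np.ndarray:
    """Centre crop of a cubic volume to `size` voxels per edge."""
    n = vol.shape[0]
    if size > n:
        raise ValueError(f"crop size {size} exceeds volume size {n}")
    a = (n - size) // 2
    return vol[a:a + size, a:a + size, a:a + size]


def extract(tomo: Tomogram, mask: np.ndarray | None, count: int, cube_size: int,
            rng_seed: int, split: bool = False) -> SubTomogramSet:
    """Box out `count` cubes at random seeds; invert contrast, then normalize.

    Contrast inversion (negation) puts density white, matching the convention
    the network is trained under.  Normalization is per cube.  With
    ``split=True`` cubes are assigned at random to two halves for
    gold-standard processing.
    """
    if mask is None:
        mask = np.ones(tomo.shape, dtype=bool)
    seeds = sample_seeds(mask, count, cube_size, rng_seed)
    m = cube_size // 2
    cubes = np.empty((count, cube_size, cube_size, cube_size), dtype=np.float32)
    transforms = []
    for i, (z, y, x) in enumerate(seeds):
        raw = tomo.data[z - m:z - m + cube_size,
                        y - m:y - m + cube_size,
                        x - m:x - m + cube_size]
        norm, t = normalize_percentile(-raw.astype(np.float32))
        cubes[i] = norm
        transforms.append(t)
    half_id = None
    if split:
        rng = np.random.default_rng(rng_seed + 1)
        half_id = np.zeros(count, dtype=int)
        half_id[rng.permutation(count)[:count // 2]] = 1
        # convention: half 0 has ceil(n/2) members, half 1 floor(n/2)
    return SubTomogramSet(cubes, seeds, tomo.name, half_id, transforms)


def make_training_pair(cube: np.ndarray, r: Rotation, w: WedgeSpec,
                       crop_size: int) -> TrainingPair:
    """Rotate, re-impose the wedge, and centre-crop into an (input, target) pair."""
    rotated = geometry.rotate_volume(cube, r)
    filt = geometry.wedge_filter(rotated.shape, w)
    filtered = geometry.apply_fourier_filter(rotated, filt)
    return TrainingPair(
        input=np.ascontiguousarray(center_crop(filtered, crop_size), dtype=np.float32),
        target=np.ascontiguousarray(center_crop(rotated, crop_size), dtype=np.float32),
        rotation=r,
    )


def build_epoch_dataset(cubes: SubTomogramSet | np.ndarray, w: WedgeSpec,
                        crop_size: int, rng_seed: int) -> list[TrainingPair]:
    """All cube x rotation training pairs, deterministically shuffled.

    The 20 wedge-moving rotations enlarge the dataset twenty-fold.
    """
    arr = cubes.cubes if isinstance(cubes, SubTomogramSet) else np.asarray(cubes)
    if len(arr) == 0:
        raise ValueError("no cubes to build a dataset from")
    rotations = geometry.training_rotations(w)
    filt = geometry.wedge_filter(arr.shape[1:], w)
    pairs = []
    for i, cube in enumerate(arr):
        for r in rotations:
            rotated = geometry.rotate_volume(cube, r)
            filtered = geometry.apply_fourier_filter(rotated, filt)
            pairs.append(TrainingPair(
                input=np.ascontiguousarray(center_crop(filtered, crop_size),
                                           dtype=np.float32),
                target=np.ascontiguousarray(center_crop(rotated, crop_size),
                                            dtype=np.float32),
                rotation=r,
                source_index=i,
            ))
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(pairs))
    return [pairs[j] for j in order]
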