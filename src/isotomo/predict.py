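"""Apply a trained network to full tomograms with the overlap-tile strategy.

The tomogram is split into disjoint core regions; each core is read together
with a `margin` of surrounding context (the volume is symmetrically padded at
its boundaries), the network predicts the padded chunk, and only the core is
written back.  Cores tile the volume exactly, so no voxel is written twice or
missed and chunk borders leave no seams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sampling import normalize_percentile
from .tomio import Tomogram

__all__ = ["TilePlan", "plan_tiles", "predict_full"]


@dataclass
class Tile:
    core_out: tuple      # slices into the output volume
    window: tuple        # slices into the padded volume (edge crop_size)
    core_in: tuple       # slices into the predicted window


@dataclass
class TilePlan:
    tiles: list
    crop_size: int
    margin: int
    pad: tuple           # ((lo, hi), ...) padding applied per axis


def plan_tiles(shape, crop_size: int, margin: int) -> TilePlan:
    """Plan disjoint cores of stride `crop_size - 2*margin` covering `shape`."""
    if crop_size <= 2 * margin:
        raise ValueError(f"margin {margin} too large for crop_size {crop_size}")
    stride = crop_size - 2 * margin
    pad, starts = [], []
    for dim in shape:
        n_tiles = max(1, -(-dim // stride))
        needed = (n_tiles - 1) * stride + crop_size
        pad.append((margin, needed - dim - margin))
        starts.append([t * stride for t in range(n_tiles)])
    tiles = []
    for sz in starts[0]:
        for sy in starts[1]:
            for sx in starts[2]:
                core_out, window, core_in = [], [], []
                for s, dim in zip((sz, sy, sx), shape):
                    end = min(s + stride, dim)
                    core_out.append(slice(s, end))
                    window.append(slice(s, s + crop_size))
                    core_in.append(slice(margin, margin + (end - s)))
                tiles.append(Tile(tuple(core_out), tuple(window), tuple(core_in)))
    return TilePlan(tiles, crop_size, margin, tuple(pad))


def _pad_symmetric(data: np.ndarray, pad) -> np.ndarray:
    """np.pad 'symmetric', applied repeatedly if a pad exceeds the axis size."""
    while True:
        this = [(min(lo, s), min(hi, s)) for (lo, hi), s in zip(pad, data.shape)]
        data = np.pad(data, this, mode="symmetric")
        pad = [(lo - t[0], hi - t[1]) for (lo, hi), t in zip(pad, this)]
        if all(lo == 0 and hi == 0 for lo, hi in pad):
            return data


def predict_full(tomo: Tomogram, model, crop_size: int,
                 margin: int | None = None, batch_size: int = 4) -> Tomogram:
    """Missing-wedge correct a whole tomogram by seamless tiled inference.

    The volume is contrast-inverted and percentile-normalized once (a single
    tomogram-level transform, so tiles share one intensity frame), predicted
    tile by tile, then mapped back to the original intensity frame.
    """
    if margin is None:
        margin = crop_size // 4
    normalized, t = normalize_percentile(-np.asarray(tomo.data, dtype=np.float32))
    plan = plan_tiles(tomo.shape, crop_size, margin)
    padded = _pad_symmetric(normalized, plan.pad)
    out = np.empty_like(normalized)
    for lo in range(0, len(plan.tiles), batch_size):
        batch = plan.tiles[lo:lo + batch_size]
        chunk = np.stack([padded[tile.window] for tile in batch])
        pred = model.predict(chunk)
        for tile, p in zip(batch, pred):
            out[tile.core_out] = p[tile.core_in]
    restored = -t.invert(out)
    return tomo.with_data(restored.astype(np.float32), suffix="_corrected")
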