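"""A 3D U-Net restoration network built from the explicit-gradient layers.

Architecture: ``depth`` encoder blocks (each a stack of same-size 3x3x3
convolutions with ReLU, one dropout per block, followed by a stride-2
convolution that halves the spatial extent and doubles the channel width), a
bottom convolution block, and a symmetric decoder that upsamples with
transposed convolutions and concatenates the equal-resolution encoder
features (skip connections).  A final 1x1x1 linear convolution maps back to a
single channel the same size as the input cube.
"""

from __future__ import annotations

import json

import numpy as np

from .layers import Conv3d, ConvTranspose3d, Dropout, ReLU


class _Block:
    """A stack of same-size convolutions + ReLUs with one trailing dropout."""

    def __init__(self, cin, width, n_convs, dropout_rate, rng):
        self.layers = []
        ch = cin
        for _ in range(n_convs):
            self.layers.append(Conv3d(ch, width, k=3, stride=1, rng=rng))
            self.layers.append(ReLU())
            ch = width
        self.dropout = Dropout(dropout_rate)

    def forward(self, x, train, rng):
        for lay in self.layers:
            x = lay.forward(x, train, rng)
        return self.dropout.forward(x, train, rng)

    def backward(self, dy):
        dy = self.dropout.backward(dy)
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy

    def parameters(self):
        out = []
        for lay in self.layers:
            out.extend(lay.parameters())
        return out


class UNet3D:
    """Volumetric encoder-decoder with skip connections.

    Input cubes must have edge length divisible by 2**depth.
    """

    def __init__(self, depth=3, base_channels=32, convs_per_block=3,
                 dropout_rate=0.5, rng_seed=0):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.config = dict(depth=depth, base_channels=base_channels,
                           convs_per_block=convs_per_block,
                           dropout_rate=dropout_rate)
        rng = np.random.default_rng(rng_seed)
        widths = [base_channels * 2 ** i for i in range(depth + 1)]
        self.depth = depth
        self.enc_blocks, self.down_convs = [], []
        ch = 1
        for i in range(depth):
            self.enc_blocks.append(_Block(ch, widths[i], convs_per_block,
                                          dropout_rate, rng))
            self.down_convs.append(Conv3d(widths[i], widths[i + 1], k=3,
                                          stride=2, rng=rng))
            self.down_relus = getattr(self, "down_relus", [])
            self.down_relus.append(ReLU())
            ch = widths[i + 1]
        self.bottom = _Block(widths[depth], widths[depth], convs_per_block,
                             dropout_rate, rng)
        self.up_convs, self.dec_blocks = [], []
        for i in reversed(range(depth)):
            self.up_convs.append(ConvTranspose3d(widths[i + 1], widths[i], rng=rng))
            self.dec_blocks.append(_Block(2 * widths[i], widths[i],
                                          convs_per_block, dropout_rate, rng))
        self.final = Conv3d(widths[0], 1, k=1, stride=1, rng=rng)

    # -- graph execution ---------------------------------------------------

    def _check(self, x):
        for d in x.shape[1:4]:
            if d % (2 ** self.depth) != 0:
                raise ValueError(
                    f"cube size {x.shape[2:]} not divisible by 2^depth={2 ** self.depth}"
                )

    def forward(self, x, train=False, rng=None):
        x = np.asarray(x, dtype=np.float32)
        self._check(x)
        skips = []
        h = x
        for blk, down, drelu in zip(self.enc_blocks, self.down_convs, self.down_relus):
            h = blk.forward(h, train, rng)
            skips.append(h)
            h = drelu.forward(down.forward(h, train, rng), train, rng)
        h = self.bottom.forward(h, train, rng)
        self._skip_channels = []
        for up, blk, skip in zip(self.up_convs, self.dec_blocks, reversed(skips)):
            h = up.forward(h, train, rng)
            self._skip_channels.append((skip.shape[-1], h.shape[-1]))
            h = np.concatenate([skip, h], axis=-1)
            h = blk.forward(h, train, rng)
        return self.final.forward(h, train, rng)

    def backward(self, dy):
        dy = self.final.backward(dy)
        dskips = []
        for up, blk, (c_skip, _) in zip(reversed(self.up_convs),
                                        reversed(self.dec_blocks),
                                        reversed(self._skip_channels)):
            dy = blk.backward(dy)
            d_skip, dy = dy[..., :c_skip], dy[..., c_skip:]
            dskips.append(d_skip)
            dy = up.backward(dy)
        dy = self.bottom.backward(dy)
        # dskips were collected shallowest-first; encoder backward runs deepest-first
        for blk, down, drelu, d_skip in zip(reversed(self.enc_blocks),
                                            reversed(self.down_convs),
                                            reversed(self.down_relus),
                                            reversed(dskips)):
            dy = down.backward(drelu.backward(dy))
            dy = dy + d_skip
            dy = blk.backward(dy)
        return dy

    # -- bookkeeping -------------------------------------------------------

    def _all_layers(self):
        out = []
        for blk in self.enc_blocks:
            out.append(blk)
        out.extend(self.down_convs)
        out.append(self.bottom)
        out.extend(self.up_convs)
        out.extend(self.dec_blocks)
        out.append(self.final)
        return out

    def parameters(self):
        out = []
        for lay in self._all_layers():
            out.extend(lay.parameters())
        return out

    def zero_grad(self):
        for _, g in self.parameters():
            g[...] = 0.0

    @property
    def n_params(self):
        return sum(p.size for p, _ in self.parameters())

    def predict(self, cubes: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Inference on a (n, c, c, c) stack; dropout disabled, deterministic."""
        cubes = np.asarray(cubes, dtype=np.float32)
        single = cubes.ndim == 3
        if single:
            cubes = cubes[None]
        out = np.empty_like(cubes)
        for i in range(0, len(cubes), batch_size):
            out[i:i + batch_size] = self.forward(
                cubes[i:i + batch_size, ..., None], train=False)[..., 0]
        return out[0] if single else out

    # -- serialization -----------------------------------------------------

    def save(self, path):
        arrays = {f"p{i}": p for i, (p, _) in enumerate(self.parameters())}
        np.savez(path, manifest=json.dumps({"format": 1, **self.config}), **arrays)

    @classmethod
    def load(cls, path):
        with np.load(path, allow_pickle=False) as z:
            manifest = json.loads(str(z["manifest"]))
            cfg = {k: manifest[k] for k in
                   ("depth", "base_channels", "convs_per_block", "dropout_rate")}
            model = cls(**cfg, rng_seed=0)
            params = model.parameters()
            for i, (p, _) in enumerate(params):
                p[...] = z[f"p{i}"]
        return model
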