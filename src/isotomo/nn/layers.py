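"""Volumetric layers with explicit reverse-mode gradients.

Activations are float32 arrays in channels-last layout (N, D, H, W, C),
which lets every convolution run as a single im2col + GEMM.  Each layer
caches what its backward pass needs during forward; ``backward`` returns the
gradient with respect to its input and accumulates parameter gradients in
place (``gW``/``gb``), which the optimizer consumes.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Conv3d:
    """3D convolution, kernel k in {1, 3}, 'same' zero padding, stride 1 or 2.

    Weights are stored as (k, k, k, cin, cout) so the im2col column order
    (window offsets fastest over cin) matches a flat reshape.
    """

    def __init__(self, cin, cout, k=3, stride=1, rng=None):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = k // 2
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (cin * k ** 3))  # He initialization
        self.W = rng.standard_normal((k, k, k, cin, cout)).astype(np.float32) * std
        self.b = np.zeros(cout, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def parameters(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def _cols(self, xp, out_spatial):
        """im2col: (N*Do*Ho*Wo, k^3*cin) from the padded input."""
        k, s = self.k, self.stride
        win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
        win = win[:, ::s, ::s, ::s]
        # win: (N, Do, Ho, Wo, C, k, k, k) -> columns ordered (k,k,k,C)
        win = win.transpose(0, 1, 2, 3, 5, 6, 7, 4)
        M = win.shape[0] * np.prod(out_spatial)
        return np.ascontiguousarray(win).reshape(M, k ** 3 * self.cin)

    def forward(self, x, train=False, rng=None):
        N = x.shape[0]
        k, s, p = self.k, self.stride, self.pad
        spatial = x.shape[1:4]
        out_spatial = tuple((d + 2 * p - k) // s + 1 for d in spatial)
        xp = (np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
              if p else x)
        self._xp, self._in_spatial, self._out_spatial = xp, spatial, out_spatial
        cols = self._cols(xp, out_spatial)
        y = cols @ self.W.reshape(-1, self.cout)
        y += self.b
        return y.reshape(N, *out_spatial, self.cout)

    def backward(self, dy):
        N = dy.shape[0]
        k, s, p = self.k, self.stride, self.pad
        Do, Ho, Wo = self._out_spatial
        dym = dy.reshape(-1, self.cout)
        self.gb += dym.sum(axis=0)
        cols = self._cols(self._xp, self._out_spatial)
        self.gW += (cols.T @ dym).reshape(self.W.shape)
        dcols = dym @ self.W.reshape(-1, self.cout).T
        dcols = dcols.reshape(N, Do, Ho, Wo, k, k, k, self.cin)
        dxp = np.zeros_like(self._xp)
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    dxp[:, a:a + s * (Do - 1) + 1:s,
                        b:b + s * (Ho - 1) + 1:s,
                        c:c + s * (Wo - 1) + 1:s, :] += dcols[:, :, :, :, a, b, c, :]
        self._xp = None
        if p:
            D, H, W = self._in_spatial
            return dxp[:, p:p + D, p:p + H, p:p + W, :]
        return dxp

    @property
    def n_params(self):
        return self.W.size + self.b.size


class ConvTranspose3d:
    """Transposed 3D convolution, kernel 2, stride 2 (exact x2 upsampling)."""

    def __init__(self, cin, cout, rng=None):
        self.cin, self.cout = cin, cout
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / cin)
        self.W = rng.standard_normal((2, 2, 2, cin, cout)).astype(np.float32) * std
        self.b = np.zeros(cout, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def parameters(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def forward(self, x, train=False, rng=None):
        N, D, H, W, C = x.shape
        xm = x.reshape(-1, C)
        self._xm, self._in_shape = xm, x.shape
        y = np.empty((N, 2 * D, 2 * H, 2 * W, self.cout), dtype=np.float32)
        for a in range(2):
            for b in range(2):
                for c in range(2):
                    ym = xm @ self.W[a, b, c] + self.b
                    y[:, a::2, b::2, c::2, :] = ym.reshape(N, D, H, W, self.cout)
        return y

    def backward(self, dy):
        N, D, H, W, C = self._in_shape
        xm = self._xm
        dxm = np.zeros_like(xm)
        for a in range(2):
            for b in range(2):
                for c in range(2):
                    dym = np.ascontiguousarray(
                        dy[:, a::2, b::2, c::2, :]).reshape(-1, self.cout)
                    self.gb += dym.sum(axis=0)
                    self.gW[a, b, c] += xm.T @ dym
                    dxm += dym @ self.W[a, b, c].T
        self._xm = None
        return dxm.reshape(N, D, H, W, C)

    @property
    def n_params(self):
        return self.W.size + self.b.size


class ReLU:
    def parameters(self):
        return []

    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx

    n_params = 0


class Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, rate=0.5):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def parameters(self):
        return []

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        rng = rng or np.random.default_rng()
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx

    n_params = 0
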