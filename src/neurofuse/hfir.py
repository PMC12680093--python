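"""High-Frequency Information Retention (HFIR) block.

Halves the in-plane resolution of the T2 volume without discarding
information: two shallow per-slice 3x3 convolutions (1 -> C -> C/r^2
channels) followed by a pixel-unshuffle (space-to-depth) step that moves
each r x r spatial block into r^2 channels.  The unshuffle is a pure index
bijection, so the downsampling itself is lossless; the convolutions learn
which high-frequency content to route through it.

With the defaults (C=16, r=2) an 18x512x512 T2 volume becomes a
16-channel 18x256x256 feature volume, spatially aligned with the DWI grid.
"""

from __future__ import annotations

import numpy as np

from .nn import Conv3d, Module, Tensor
from .nn import functional as F


class HfirShapeError(ValueError):
    pass


def pixel_unshuffle(v: np.ndarray, r: int) -> np.ndarray:
    """Space-to-depth on a (B, C, D, H, W) volume; H, W must divide by r.

    out[b, c*r^2 + dh*r + dw, d, i, j] = v[b, c, d, i*r + dh, j*r + dw]
    (row-major polyphase ordering).
    """
    try:
        return F.pixel_unshuffle_array(np.asarray(v), r)
    except ValueError as e:
        raise HfirShapeError(str(e)) from e


def pixel_shuffle(v: np.ndarray, r: int) -> np.ndarray:
    """Exact inverse of :func:`pixel_unshuffle`."""
    try:
        return F.pixel_shuffle_array(np.asarray(v), r)
    except ValueError as e:
        raise HfirShapeError(str(e)) from e


class HFIR(Module):
    """conv 1->C, conv C->C/r^2 (both 3x3 per depth-slice), pixel-unshuffle r.

    Output shape: (B, C, D, H/r, W/r).  Purely linear + permutation by
    default; ``nonlinearity=True`` inserts a ReLU between the convolutions.
    """

    def __init__(self, channels: int = 16, r: int = 2, nonlinearity: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if r < 1:
            raise ValueError(f"unshuffle factor must be >= 1, got {r}")
        if channels % (r * r):
            raise ValueError(f"C={channels} must be divisible by r^2={r * r}")
        rng = rng or np.random.default_rng(0)
        self.channels, self.r = channels, r
        self.nonlinearity = nonlinearity
        self.conv_a = Conv3d(1, channels, (1, 3, 3), padding=(0, 1, 1), rng=rng)
        self.conv_b = Conv3d(channels, channels // (r * r), (1, 3, 3),
                             padding=(0, 1, 1), rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != 1:
            raise HfirShapeError(f"HFIR expects a single-channel input, "
                                 f"got {x.shape[1]} channels")
        if x.shape[3] % self.r or x.shape[4] % self.r:
            raise HfirShapeError(
                f"spatial dims {x.shape[3:]} not divisible by r={self.r}")
        s = self.conv_a(x)
        if self.nonlinearity:
            s = s.relu()
        s = self.conv_b(s)
        return F.pixel_unshuffle(s, self.r)


def hfir_forward(x, block: HFIR) -> np.ndarray:
    """Convenience: run the block on a plain array, returning an array."""
    return block(Tensor(np.asarray(x, dtype=np.float32))).data
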