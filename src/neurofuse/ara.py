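"""Adaptive Region Attention (ARA): cross-modal gating of region tokens.

Both branches' layer-4 feature maps are flattened into region-token
sequences (one token per voxel of the feature grid, C channels each).  The
concatenated token f = [fT2, fDWI] (2C channels) passes through a shared
two-layer bottleneck

    Gamma = sigmoid( ReLU(f Phi1 + b1) Phi2 + b2 ),   Phi1: 2C x C/2,
                                                      Phi2: C/2 x 2C,

and Gamma splits back into per-modality gates.  Each branch is rescaled with
a residual skip:

    alpha_m = Gamma_m * f_m + f_m = (1 + Gamma_m) * f_m,   m in {T2, DWI},

so gate scores in (0, 1) can only amplify (by at most 2x), never suppress a
feature's sign or zero it out.  The FC layers act identically on every
token; the module mixes modalities, not regions.

Token layout is depth-major over the full 3D grid (P = D*H*W) by default —
the only lossless flattening of a volumetric map; ``tokens='hw-slicewise'``
instead gates each depth slice independently with P = H*W.
"""

from __future__ import annotations

import numpy as np

from .nn import Linear, Module, Tensor, concat


class AraShapeError(ValueError):
    pass


def flatten_regions(f: Tensor | np.ndarray) -> Tensor:
    """(B, C, D, H, W) -> (B, P, C) with token index = d*H*W + h*W + w."""
    t = f if isinstance(f, Tensor) else Tensor(np.asarray(f))
    B, C = t.shape[:2]
    P = int(np.prod(t.shape[2:]))
    return t.reshape(B, C, P).transpose(0, 2, 1)


def unflatten_regions(seq: Tensor | np.ndarray, grid_shape) -> Tensor:
    """(B, P, C) -> (B, C, D, H, W); exact inverse of flatten_regions."""
    t = seq if isinstance(seq, Tensor) else Tensor(np.asarray(seq))
    B, P, C = t.shape
    D, H, W = grid_shape
    if P != D * H * W:
        raise AraShapeError(f"{P} tokens cannot fill grid {tuple(grid_shape)}")
    return t.transpose(0, 2, 1).reshape(B, C, D, H, W)


class AraGate(Module):
    """The gating network; ``channels`` is C, the per-branch width."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        if channels % 2:
            raise ValueError(f"C must be even, got {channels}")
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.fc1 = Linear(2 * channels, channels // 2, rng=rng)  # Phi1, b1
        self.fc2 = Linear(channels // 2, 2 * channels, rng=rng)  # Phi2, b2

    def forward(self, f_t2: Tensor, f_dwi: Tensor):
        if f_t2.shape != f_dwi.shape:
            raise AraShapeError(
                f"branch sequences disagree: {f_t2.shape} vs {f_dwi.shape}")
        if f_t2.shape[-1] != self.channels:
            raise AraShapeError(
                f"expected C={self.channels}, got {f_t2.shape[-1]}")
        f = concat([f_t2, f_dwi], axis=-1)                 # (B, P, 2C)
        gamma = self.fc2(self.fc1(f).relu()).sigmoid()     # (B, P, 2C)
        C = self.channels
        g_t2 = _slice_last(gamma, 0, C)
        g_dwi = _slice_last(gamma, C, 2 * C)
        return g_t2 * f_t2 + f_t2, g_dwi * f_dwi + f_dwi


def _slice_last(t: Tensor, a: int, b: int) -> Tensor:
    data = t.data[..., a:b]

    def bwd(g):
        full = np.zeros_like(t.data)
        full[..., a:b] = g
        t._accum(full)

    return Tensor._make(data, (t,), bwd, t.requires_grad)


def ara_gate(f_t2, f_dwi, gate: AraGate):
    """Run the gate on plain arrays; returns (alpha_t2, alpha_dwi) arrays."""
    a, b = gate(Tensor(np.asarray(f_t2)), Tensor(np.asarray(f_dwi)))
    return a.data, b.data


def fuse_attended(alpha_t2: Tensor | np.ndarray, alpha_dwi: Tensor | np.ndarray,
                  grid_shape) -> Tensor:
    """Concatenate the attended sequences channelwise and restore the grid:
    (B, P, C) x 2 -> (B, 2C, D, H, W)."""
    a = alpha_t2 if isinstance(alpha_t2, Tensor) else Tensor(np.asarray(alpha_t2))
    b = alpha_dwi if isinstance(alpha_dwi, Tensor) else Tensor(np.asarray(alpha_dwi))
    if a.shape != b.shape:
        raise AraShapeError(f"attended sequences disagree: {a.shape} vs {b.shape}")
    return unflatten_regions(concat([a, b], axis=-1), grid_shape)
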