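"""Dual-branch feature extractor: 3D ResNet-18.

Standard basic-block residual topology (two 3x3x3 convolutions per block,
widths 64/128/256/512, two blocks per stage) generalized to volumes.  The
in-plane stride plan follows 2D ResNet (stem /2, pool /2, stages 1,2,2,2);
the through-plane (depth) plan is chosen so that an 18-slice input reaches
a 4-slice layer-4 map: stem and pool keep depth, stages stride (1, 1, 2, 2)
with depth padding 1 except stage 4 (padding 0), giving 18 -> 18 -> 9 -> 4.
Projection shortcuts use a (3, 1, 1) kernel with the same depth padding so
both paths of a block agree on output size for every valid input.

Layer 4 (the final residual stage) always has ``stage_widths[-1]`` channels
regardless of input size; for the default widths that is 512, and a
(18, 256, 256) input yields the (512, 4, 8, 8) feature map consumed by the
region-attention fusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm3d, Conv3d, Module, Tensor
from .nn import functional as F
from .nn.functional import conv_out_size


class PlanError(ValueError):
    pass


@dataclass(frozen=True)
class BackbonePlan:
    """Stride/padding bookkeeping for one backbone branch."""

    in_channels: int = 3
    stage_widths: tuple[int, int, int, int] = (64, 128, 256, 512)
    blocks_per_stage: tuple[int, int, int, int] = (2, 2, 2, 2)
    stem_kernel: tuple[int, int, int] = (3, 7, 7)
    stem_stride: tuple[int, int, int] = (1, 2, 2)
    stem_padding: tuple[int, int, int] = (1, 3, 3)
    pool_kernel: tuple[int, int, int] = (1, 3, 3)
    pool_stride: tuple[int, int, int] = (1, 2, 2)
    pool_padding: tuple[int, int, int] = (0, 1, 1)
    stage_spatial_strides: tuple[int, int, int, int] = (1, 2, 2, 2)
    stage_depth_strides: tuple[int, int, int, int] = (1, 1, 2, 2)
    stage_depth_padding: tuple[int, int, int, int] = (1, 1, 1, 0)
    norm_mode: str = "batch"  # or "instance" for batch-size-1 LOOCV edge cases

    def stage_specs(self):
        """Per-stage (stride_dhw, padding_dhw) of the downsampling conv."""
        return [((d, s, s), (pd, 1, 1)) for d, s, pd in
                zip(self.stage_depth_strides, self.stage_spatial_strides,
                    self.stage_depth_padding)]


def tiny_plan(in_channels=3, norm_mode="instance") -> BackbonePlan:
    """Width-reduced plan for CPU-scale training.

    Strides are relaxed (total /8 in-plane, /2 in depth) so that the
    reduced-resolution input grid (8, 64, 64) reaches the same printed
    layer-4 geometry (4, 8, 8) as the full-size plan does from
    (18, 256, 256) — region-token count and Grad-CAM granularity match
    the full model.
    """
    return BackbonePlan(in_channels=in_channels, stage_widths=(4, 8, 16, 32),
                        stage_spatial_strides=(1, 2, 1, 1),
                        stage_depth_strides=(1, 1, 2, 1),
                        stage_depth_padding=(1, 1, 1, 1),
                        norm_mode=norm_mode)


def shape_plan(input_shape, plan: BackbonePlan) -> list[tuple[int, int, int]]:
    """Pure stride arithmetic: per-stage (D, H, W) after stem, pool, stages 1-4.

    Raises PlanError if any stage would collapse an axis below 1.
    """

    def step(shape, kernel, stride, padding):
        try:
            return tuple(conv_out_size(n, k, s, p) for n, k, s, p in
                         zip(shape, kernel, stride, padding))
        except ValueError as e:
            raise PlanError(str(e)) from e

    shapes = []
    cur = step(tuple(input_shape), plan.stem_kernel, plan.stem_stride,
               plan.stem_padding)
    shapes.append(cur)
    cur = step(cur, plan.pool_kernel, plan.pool_stride, plan.pool_padding)
    shapes.append(cur)
    for stride, padding in plan.stage_specs():
        cur = step(cur, (3, 3, 3), stride, padding)
        shapes.append(cur)
    return shapes


class BasicBlock(Module):
    """conv-norm-relu-conv-norm + shortcut, relu after the sum."""

    def __init__(self, in_ch, out_ch, stride, depth_padding, norm_mode, rng):
        super().__init__()
        pad = (depth_padding, 1, 1)
        self.conv1 = Conv3d(in_ch, out_ch, 3, stride=stride, padding=pad,
                            bias=False, rng=rng)
        self.bn1 = BatchNorm3d(out_ch, mode=norm_mode)
        self.conv2 = Conv3d(out_ch, out_ch, 3, stride=1, padding=1,
                            bias=False, rng=rng)
        self.bn2 = BatchNorm3d(out_ch, mode=norm_mode)
        if in_ch != out_ch or stride != (1, 1, 1):
            # (3,1,1) kernel with the block's depth padding keeps the
            # shortcut's output size identical to the residual path's
            self.proj = Conv3d(in_ch, out_ch, (3, 1, 1), stride=stride,
                               padding=(depth_padding, 0, 0), bias=False, rng=rng)
            self.proj_bn = BatchNorm3d(out_ch, mode=norm_mode)
        else:
            self.proj = None

    def forward(self, x):
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        sc = x if self.proj is None else self.proj_bn(self.proj(x))
        return (out + sc).relu()


class Backbone3D(Module):
    """3D ResNet-18 trunk; ``forward`` returns the layer-4 feature map."""

    def __init__(self, plan: BackbonePlan, rng: np.random.Generator):
        super().__init__()
        self.plan = plan
        w = plan.stage_widths
        self.stem = Conv3d(plan.in_channels, w[0], plan.stem_kernel,
                           stride=plan.stem_stride, padding=plan.stem_padding,
                           bias=False, rng=rng)
        self.stem_bn = BatchNorm3d(w[0], mode=plan.norm_mode)
        self.stages = []
        in_ch = w[0]
        for width, n_blocks, (stride, padding) in zip(
                w, plan.blocks_per_stage, plan.stage_specs()):
            blocks = [BasicBlock(in_ch, width, stride, padding[0],
                                 plan.norm_mode, rng)]
            blocks += [BasicBlock(width, width, (1, 1, 1), 1,
                                  plan.norm_mode, rng)
                       for _ in range(n_blocks - 1)]
            self.stages.append(blocks)
            in_ch = width

    @property
    def out_channels(self) -> int:
        return self.plan.stage_widths[-1]

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.plan.in_channels:
            raise PlanError(f"backbone expects {self.plan.in_channels} input "
                            f"channels, got {x.shape[1]}")
        x = self.stem_bn(self.stem(x)).relu()
        x = F.max_pool3d(x, self.plan.pool_kernel, self.plan.pool_stride,
                         self.plan.pool_padding)
        self._stage_outputs = []  # per-stage activations (Grad-CAM taps)
        for blocks in self.stages:
            for block in blocks:
                x = block(x)
            self._stage_outputs.append(x)
        return x

    def stage_activation(self, stage: int) -> Tensor:
        """Activation of stage 1..4 (or -1 for layer 4) from the latest
        forward pass."""
        if not getattr(self, "_stage_outputs", None):
            raise PlanError("no forward pass recorded")
        return self._stage_outputs[stage if stage < 0 else stage - 1]


def build_backbone(plan: BackbonePlan, seed: int) -> Backbone3D:
    """Randomly initialized backbone; bit-identical for identical seeds."""
    return Backbone3D(plan, np.random.default_rng(seed))


def extract_layer4(backbone: Backbone3D, v) -> Tensor:
    """Final residual stage activation for a (B, C, D, H, W) volume."""
    x = v if isinstance(v, Tensor) else Tensor(np.asarray(v, dtype=np.float32))
    return backbone(x)
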