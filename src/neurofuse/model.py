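"""Full model assembly: HFIR -> dual 3D ResNet-18 branches -> ARA -> head.

Five variants cover the ablation lattice:

* ``dwi_only``       — DWI branch alone (3 b-value channels);
* ``t2_only``        — raw T2 branch alone (full resolution, 1 channel);
* ``t2_hfir_only``   — HFIR-downsampled T2 branch alone;
* ``concat_no_ara``  — both branches, channel concatenation, no gating;
* ``full``           — both branches with ARA gating before fusion.

The classification head is dropout -> 1x1x1 conv (to 3 classes) -> global
average pool.  No rectification is applied after the classifier conv (it
would forbid negative logits under cross-entropy); an optional ReLU on the
fused features before the conv is available via ``head_relu``.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

import numpy as np

from .ara import AraGate, flatten_regions, fuse_attended
from .backbone import Backbone3D, BackbonePlan
from .hfir import HFIR
from .nn import Conv3d, Dropout, Module, Tensor
from .nn import functional as F

VARIANTS = ("dwi_only", "t2_only", "t2_hfir_only", "concat_no_ara", "full")


class ModelConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    variant: str = "full"
    n_classes: int = 3
    dropout_p: float = 0.5
    hfir_channels: int = 16
    hfir_r: int = 2
    stage_widths: tuple[int, int, int, int] = (64, 128, 256, 512)
    stage_spatial_strides: tuple[int, int, int, int] = (1, 2, 2, 2)
    stage_depth_strides: tuple[int, int, int, int] = (1, 1, 2, 2)
    stage_depth_padding: tuple[int, int, int, int] = (1, 1, 1, 0)
    norm_mode: str = "batch"
    head_relu: bool = False
    tokens: str = "dhw"  # or "hw-slicewise"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ModelConfigError(
                f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ModelConfigError("dropout_p must be in [0, 1)")
        if self.tokens not in ("dhw", "hw-slicewise"):
            raise ModelConfigError(f"unknown token layout {self.tokens!r}")


def tiny_model_config(variant="full", **kw) -> ModelConfig:
    """Width-reduced configuration matching the tiny phantom preset.

    Instance normalization replaces batch statistics: with a handful of
    optimizer steps per LOOCV fold, batch-norm running averages never burn
    in, while instance statistics behave identically in train and eval.
    Dropout is disabled: at ~100 optimizer steps per fold the 0.5-dropout
    noise of the full preset prevents convergence altogether.
    """
    kw.setdefault("stage_widths", (4, 8, 16, 32))
    kw.setdefault("hfir_channels", 8)
    kw.setdefault("norm_mode", "instance")
    kw.setdefault("dropout_p", 0.0)
    # relaxed strides: the (8, 64, 64) grid reaches the same (4, 8, 8)
    # layer-4 geometry as the full-size plan (see backbone.tiny_plan)
    kw.setdefault("stage_spatial_strides", (1, 2, 1, 1))
    kw.setdefault("stage_depth_strides", (1, 1, 2, 1))
    kw.setdefault("stage_depth_padding", (1, 1, 1, 1))
    return ModelConfig(variant=variant, **kw)


class TumorClassifier(Module):
    """Three-way normal/benign/malignant classifier over paired DWI + T2."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        v = config.variant
        C = config.stage_widths[-1]

        def plan(in_ch):
            return BackbonePlan(in_channels=in_ch,
                                stage_widths=config.stage_widths,
                                stage_spatial_strides=config.stage_spatial_strides,
                                stage_depth_strides=config.stage_depth_strides,
                                stage_depth_padding=config.stage_depth_padding,
                                norm_mode=config.norm_mode)

        self.hfir = None
        self.backbone_dwi = None
        self.backbone_t2 = None
        self.ara = None
        if v in ("full", "concat_no_ara", "t2_hfir_only"):
            self.hfir = HFIR(config.hfir_channels, config.hfir_r, rng=rng)
        if v in ("full", "concat_no_ara", "dwi_only"):
            self.backbone_dwi = Backbone3D(plan(3), rng)
        if v in ("full", "concat_no_ara"):
            self.backbone_t2 = Backbone3D(plan(config.hfir_channels), rng)
        elif v == "t2_hfir_only":
            self.backbone_t2 = Backbone3D(plan(config.hfir_channels), rng)
        elif v == "t2_only":
            self.backbone_t2 = Backbone3D(plan(1), rng)
        if v == "full":
            self.ara = AraGate(C, rng=rng)

        head_in = 2 * C if v in ("full", "concat_no_ara") else C
        self.dropout = Dropout(config.dropout_p)
        self.classifier = Conv3d(head_in, config.n_classes, 1, rng=rng)
        # retained layer-4 activations of the latest forward (Grad-CAM hooks)
        self.activations: dict[str, Tensor] = {}

    # ------------------------------------------------------------------ head
    def head(self, fused: Tensor) -> Tensor:
        """dropout -> 1x1x1 conv -> global average pool -> (B, n_classes)."""
        if fused.shape[1] != self.classifier.weight.shape[1]:
            raise ModelConfigError(
                f"head expects {self.classifier.weight.shape[1]} channels, "
                f"got {fused.shape[1]}")
        x = self.dropout(fused)
        if self.config.head_relu:
            x = x.relu()
        x = self.classifier(x)
        return x.mean(axis=(2, 3, 4))

    # --------------------------------------------------------------- forward
    def forward(self, dwi: Tensor | None, t2: Tensor | None) -> Tensor:
        v = self.config.variant
        self.activations = {}

        def as_tensor(x):
            if x is None:
                return None
            return x if isinstance(x, Tensor) else Tensor(
                np.asarray(x, dtype=np.float32))

        dwi, t2 = as_tensor(dwi), as_tensor(t2)
        if v == "dwi_only":
            f = self.backbone_dwi(self._req(dwi, "dwi"))
            self.activations["dwi"] = f
            return self.head(f)
        if v == "t2_only":
            f = self.backbone_t2(self._req(t2, "t2"))
            self.activations["t2"] = f
            return self.head(f)
        if v == "t2_hfir_only":
            f = self.backbone_t2(self.hfir(self._req(t2, "t2")))
            self.activations["t2"] = f
            return self.head(f)

        f_dwi = self.backbone_dwi(self._req(dwi, "dwi"))
        f_t2 = self.backbone_t2(self.hfir(self._req(t2, "t2")))
        if f_dwi.shape != f_t2.shape:
            raise ModelConfigError(
                f"branch feature maps disagree: DWI {f_dwi.shape}, "
                f"T2 {f_t2.shape}; check the 2x modality geometry")
        self.activations["dwi"], self.activations["t2"] = f_dwi, f_t2
        grid = f_dwi.shape[2:]

        if v == "concat_no_ara":
            from .nn.tensor import concat
            return self.head(concat([f_t2, f_dwi], axis=1))

        # tokens="dhw": P = D*H*W; tokens="hw-slicewise": P = H*W with depth
        # folded into the batch axis. The gate acts per token, so both are
        # the same arithmetic on a different batch layout.
        if self.config.tokens == "hw-slicewise":
            B, C, D, H, W = f_t2.shape
            fold = lambda t: t.transpose(0, 2, 1, 3, 4).reshape(B * D, C, 1, H, W)
            s_t2, s_dwi = flatten_regions(fold(f_t2)), flatten_regions(fold(f_dwi))
            a_t2, a_dwi = self.ara(s_t2, s_dwi)
            fused = fuse_attended(a_t2, a_dwi, (1, H, W))
            fused = fused.reshape(B, D, 2 * C, H, W).transpose(0, 2, 1, 3, 4)
            return self.head(fused)
        s_t2, s_dwi = flatten_regions(f_t2), flatten_regions(f_dwi)
        a_t2, a_dwi = self.ara(s_t2, s_dwi)
        from .ara import unflatten_regions
        from .nn.tensor import concat
        # keep the attended maps on the logits path so Grad-CAM can read
        # their gradients; concatenating them equals fuse_attended
        t2_att = unflatten_regions(a_t2, grid)
        dwi_att = unflatten_regions(a_dwi, grid)
        self.activations["t2_attended"] = t2_att
        self.activations["dwi_attended"] = dwi_att
        return self.head(concat([t2_att, dwi_att], axis=1))

    @staticmethod
    def _req(x, name):
        if x is None:
            raise ModelConfigError(f"variant requires a {name} input")
        return x

    # ------------------------------------------------------------ prediction
    def predict(self, dwi, t2) -> tuple[np.ndarray, np.ndarray]:
        """Eval-mode argmax labels and softmax scores for a batch."""
        was_training = self.training
        self.eval()
        logits = self.forward(dwi, t2).data
        if was_training:
            self.train()
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        return logits.argmax(axis=1), p

    # ----------------------------------------------------------- persistence
    def save(self, path):
        with open(path, "wb") as fh:
            pickle.dump({"config": self.config, "state": self.state_dict()}, fh)

    @classmethod
    def load(cls, path) -> "TumorClassifier":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        model = cls(blob["config"])
        model.load_state_dict(blob["state"])
        return model


def transfer_shared_weights(src: TumorClassifier, dst: TumorClassifier):
    """Copy weights for every submodule both variants instantiate.

    Lets the ablation harness evaluate e.g. ``concat_no_ara`` with the same
    branch weights as ``full`` where architectures overlap.
    """
    src_params = dict(src.named_parameters())
    for name, p in dst.named_parameters():
        if name in src_params and src_params[name].data.shape == p.data.shape:
            p.data = src_params[name].data.copy()


@dataclass
class CamMap:
    """3D Grad-CAM: non-negative saliency on the layer-4 grid plus a
    trilinear upsampling to the input grid; max-normalized to 1 when any
    evidence is present."""

    cam: np.ndarray
    cam_upsampled: np.ndarray
    target_class: int
    branch: str


def gradcam3d(model: TumorClassifier, dwi, t2, target_class: int,
              branch: str = "dwi", stage: int = -1) -> CamMap:
    """Gradient-weighted class activation map on a single sample.

    Channel weights are the global average of d logit[target] / d A over the
    selected branch's activation A; the CAM is the rectified
    channel-weighted sum, normalized to [0, 1].  ``stage`` selects the
    backbone stage to read (default -1: layer 4); earlier stages give finer
    grids, useful when a reduced-resolution model's layer-4 map is too
    coarse to localize on.  ``branch`` may also name an attention-gated map
    ("dwi_attended" / "t2_attended", full variant only): with the 1x1x1-conv
    + global-average-pool head, the CAM of an attended map equals the
    model's rectified spatial class-evidence exactly.
    """
    if target_class not in range(model.config.n_classes):
        raise ModelConfigError(f"target_class {target_class} out of range")
    model.eval()
    inputs = {"dwi": dwi, "t2": t2}
    ref = inputs[branch if branch in inputs and inputs[branch] is not None
                 else "dwi"]
    logits = model.forward(dwi, t2)
    if branch not in model.activations:
        raise ModelConfigError(
            f"branch {branch!r} has no layer-4 activation in variant "
            f"{model.config.variant!r}")
    if stage in (-1, 4) or not hasattr(model, f"backbone_{branch}"):
        act = model.activations[branch]
    else:
        backbone = getattr(model, f"backbone_{branch}")
        if backbone is None:
            raise ModelConfigError(f"variant has no {branch} backbone")
        act = backbone.stage_activation(stage)
    for p in model.parameters():
        p.zero_grad()
    act.zero_grad()
    seed_grad = np.zeros_like(logits.data)
    seed_grad[:, target_class] = 1.0
    logits.backward(seed_grad)

    weights = act.grad.mean(axis=(2, 3, 4), keepdims=True)  # (B, C, 1, 1, 1)
    cam = np.maximum((weights * act.data).sum(axis=1), 0.0)  # (B, D4, H4, W4)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    in_shape = np.asarray(ref).shape[-3:] if not isinstance(ref, Tensor) \
        else ref.shape[-3:]
    # corner-aligned trilinear upsample: with the stride-aligned conv plan,
    # feature voxel j sits at input voxel j*stride, so input voxel p maps to
    # feature coordinate p/stride (not the half-cell-shifted zoom grid)
    from scipy.ndimage import map_coordinates

    coords = np.meshgrid(*[np.arange(t) * (s / t) for t, s in
                           zip(in_shape, cam.shape[1:])], indexing="ij")
    up = np.stack([map_coordinates(c, coords, order=1, mode="nearest")
                   for c in cam])
    return CamMap(cam=cam, cam_upsampled=up, target_class=target_class,
                  branch=branch)
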