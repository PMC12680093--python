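"""Layer modules: parameter containers with a torch-like train/eval switch.

Weight initialization follows He fan-in scaling for convolutions and linear
layers, drawn from a numpy Generator so two builds from the same seed are
bit-identical.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor


class Module:
    """Base class; submodules and parameters are discovered by attribute scan."""

    def __init__(self):
        self.training = True

    @staticmethod
    def _children(obj, prefix):
        """(name, value) pairs one level down, descending through nested
        lists/tuples (e.g. stages of blocks)."""
        if isinstance(obj, Module):
            # underscore attributes are transient state (e.g. retained
            # activations), never parameters or buffers
            items = ((k, v) for k, v in obj.__dict__.items()
                     if not k.startswith("_"))
        elif isinstance(obj, (list, tuple)):
            items = ((str(i), v) for i, v in enumerate(obj))
        else:
            return
        for name, v in items:
            if isinstance(v, (Module, Tensor)):
                yield f"{prefix}{name}", v
            elif isinstance(v, (list, tuple)):
                yield from Module._children(v, f"{prefix}{name}.")

    def modules(self):
        yield self
        for _, v in Module._children(self, ""):
            if isinstance(v, Module):
                yield from v.modules()

    def _named_tensors(self, prefix, want_grad):
        for name, v in Module._children(self, prefix):
            if isinstance(v, Tensor):
                if v.requires_grad == want_grad:
                    yield name, v
            else:
                yield from v._named_tensors(f"{name}.", want_grad)

    def named_parameters(self, prefix=""):
        yield from self._named_tensors(prefix, True)

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def buffers(self, prefix=""):
        yield from self._named_tensors(prefix, False)

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self):
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        d.update({f"__buf__{name}": b.data.copy() for name, b in self.buffers()})
        return d

    def load_state_dict(self, d):
        for name, p in self.named_parameters():
            p.data = np.asarray(d[name]).copy()
        for name, b in self.buffers():
            key = f"__buf__{name}"
            if key in d:
                b.data = np.asarray(d[key]).copy()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in, dtype=np.float32):
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Conv3d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, bias=True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        k = F._triple(kernel)
        self.stride = F._triple(stride)
        self.padding = F._triple(padding)
        fan_in = in_ch * k[0] * k[1] * k[2]
        self.weight = Tensor(_he_init(rng, (out_ch, in_ch) + k, fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return F.conv3d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, in_features, out_features, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(_he_init(rng, (in_features, out_features), in_features),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, np.float32), requires_grad=True)

    def forward(self, x):
        return x @ self.weight + self.bias


class BatchNorm3d(Module):
    """Per-channel normalization over (B, D, H, W).

    mode='batch' uses minibatch statistics in training and running averages in
    eval; mode='instance' always uses per-sample statistics (the LOOCV
    batch-size-1 fallback).
    """

    def __init__(self, num_features, eps=1e-5, momentum=0.1, mode="batch"):
        super().__init__()
        if mode not in ("batch", "instance"):
            raise ValueError(f"unknown norm mode {mode!r}")
        self.eps, self.momentum, self.mode = eps, momentum, mode
        self.gamma = Tensor(np.ones((1, num_features, 1, 1, 1), np.float32),
                            requires_grad=True)
        self.beta = Tensor(np.zeros((1, num_features, 1, 1, 1), np.float32),
                           requires_grad=True)
        self.running_mean = Tensor(np.zeros((1, num_features, 1, 1, 1), np.float32))
        self.running_var = Tensor(np.ones((1, num_features, 1, 1, 1), np.float32))

    def forward(self, x):
        axes = (0, 2, 3, 4) if self.mode == "batch" else (2, 3, 4)
        if self.training or self.mode == "instance":
            m = x.mean(axis=axes, keepdims=True)
            xm = x - m
            v = (xm * xm).mean(axis=axes, keepdims=True)
            if self.training and self.mode == "batch":
                mom = self.momentum
                self.running_mean.data = ((1 - mom) * self.running_mean.data
                                          + mom * m.data)
                self.running_var.data = ((1 - mom) * self.running_var.data
                                         + mom * v.data)
            xhat = xm * (v + self.eps) ** -0.5
        else:
            xhat = (x - self.running_mean) * Tensor(
                (self.running_var.data + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; a no-op in eval mode. RNG is injected per forward
    epoch via set_rng so training stays reproducible."""

    def __init__(self, p=0.5):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self._rng = np.random.default_rng(0)

    def set_rng(self, rng: np.random.Generator):
        self._rng = rng

    def forward(self, x):
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self._rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * Tensor(mask)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x
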