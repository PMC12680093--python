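def _tune_allocator():
    """Keep large freed buffers on the heap (glibc): repeated mmap/munmap of
    activation-sized arrays costs more in page faults than the arithmetic."""
    try:
        import ctypes

        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-1, 1 << 30)  # M_TRIM_THRESHOLD
        libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
    except Exception:
        pass  # non-glibc platform: harmless to skip


_tune_allocator()

from .tensor import Tensor, concat
from . import functional
from .modules import (
    Module, Conv3d, Linear, BatchNorm3d, Dropout, ReLU, Sequential,
)
from .optim import AdamW, CosineAnnealingLR

__all__ = [
    "Tensor", "concat", "functional", "Module", "Conv3d", "Linear",
    "BatchNorm3d", "Dropout", "ReLU", "Sequential", "AdamW",
    "CosineAnnealingLR",
]
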