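def _tune_malloc() -> None:
    # graph-holding workloads churn >128KB temporaries; keeping glibc from
    # returning them to the kernel avoids page-fault-bound training steps
    import ctypes
    import sys
    if not sys.platform.startswith("linux"):
        return
    try:
        libc = ctypes.CDLL("libc.so.6", use_errno=True)
        libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
        libc.mallopt(-1, 1 << 30)  # M_TRIM_THRESHOLD
    except OSError:
        pass


_tune_malloc()

from .autograd import Tensor, concat, get_default_dtype, set_default_dtype
from .modules import (
    Conv2d, ConvTranspose2d, InstanceNorm2d, LeakyReLU, Linear, Module,
    ReflectionPad2d, ReLU, Sequential, Sigmoid, Tanh, glorot_uniform,
)
from .optim import Adam

__all__ = [
    "Tensor", "concat", "set_default_dtype", "get_default_dtype", "Module", "Conv2d", "ConvTranspose2d", "Linear",
    "InstanceNorm2d", "Sequential", "ReLU", "LeakyReLU", "Tanh", "Sigmoid",
    "ReflectionPad2d", "glorot_uniform", "Adam",
]
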