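"""Layer objects wrapping the autograd primitives.

He-uniform initialization throughout (appropriate for ELU/ReLU-family
activations); every layer draws from the numpy Generator it is given so a
fixed seed reproduces the network bit for bit.
"""

from __future__ import annotations

import numpy as np

from .autograd import (
    Tensor,
    batch_norm_op,
    concat,
    conv_nd,
    elu_op,
    max_pool_nd,
    softmax_op,
    zero_insert,
)


class Module:
    """Base class: parameter bookkeeping and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self):
        for m in self.modules():
            m.training = True

    def eval(self):
        for m in self.modules():
            m.training = False

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    # -- state dict (flat, ordered by discovery) --
    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]):
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError(f"state length mismatch: {len(own)} vs {len(arrays)}")
        for dst, src in zip(own, arrays):
            if dst.shape != src.shape:
                raise ValueError(f"state shape mismatch: {dst.shape} vs {src.shape}")
            dst[...] = src


def _he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv(Module):
    """3x3(x3) zero-padded convolution, stride 1, 'same' output shape."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, dims: int, rng: np.random.Generator):
        super().__init__()
        shape = (out_ch, in_ch) + (kernel,) * dims
        fan_in = in_ch * kernel**dims
        self.weight = Tensor(_he_uniform(rng, shape, fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)
        self.pad = kernel // 2

    def forward(self, x: Tensor) -> Tensor:
        return conv_nd(x, self.weight, self.bias, self.pad)


class ConvTranspose(Module):
    """Transposed convolution with stride 2: doubles each spatial dimension.

    Realised as zero-insertion followed by a same-padded convolution, which
    is equivalent to the usual kernel-3 / stride-2 / output-padding-1
    transposed convolution up to a reparameterization of the kernel.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, dims: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv(in_ch, out_ch, kernel, dims, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(zero_insert(x, 2))


class BatchNorm(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm_op(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
        )


def elu(x: Tensor) -> Tensor:
    return elu_op(x)


def max_pool(x: Tensor, size: int = 2) -> Tensor:
    return max_pool_nd(x, size)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    return softmax_op(x, axis)


def concat_channels(tensors) -> Tensor:
    return concat(tensors, axis=1)
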