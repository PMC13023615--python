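"""Layer modules built on the autodiff Tensor."""

from __future__ import annotations

import numpy as np

from specrestore.nn import autodiff as ad
from specrestore.nn.autodiff import Tensor

__all__ = ["Module", "Conv1d", "ReLU", "Sequential", "ResidualBlock", "SpectralAttention"]


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state array shape mismatch")
            p.data = np.asarray(a, dtype=p.data.dtype).copy()

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv1d(Module):
    """Same-length 1D convolution (stride 1) or strided downsampling."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        rng = rng or np.random.default_rng()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        scale = np.sqrt(2.0 / (in_channels * kernel_size))  # He init
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(out_channels, in_channels, kernel_size))
            .astype(dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)
        self.stride = stride
        self.padding = (kernel_size - 1) // 2

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv1d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ad.relu(x)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for module in self.modules:
            x = module(x)
        return x


class ResidualBlock(Module):
    """conv-relu-conv plus identity shortcut, then ReLU."""

    def __init__(self, channels, kernel_size, rng=None, dtype=np.float64):
        self.conv1 = Conv1d(channels, channels, kernel_size, rng=rng, dtype=dtype)
        self.conv2 = Conv1d(channels, channels, kernel_size, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        h = ad.relu(self.conv1(x))
        h = self.conv2(h)
        return ad.relu(ad.add(h, x))


class SpectralAttention(Module):
    """Position-wise gating: features are re-weighted by a sigmoid gate
    computed from themselves, focusing capacity on informative bands."""

    def __init__(self, channels, rng=None, dtype=np.float64):
        self.gate_conv = Conv1d(channels, channels, 1, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return ad.mul(x, ad.sigmoid(self.gate_conv(x)))
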