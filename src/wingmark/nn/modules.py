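"""Layer modules over the autodiff core: Conv2d, BatchNorm2d, ReLU, Sequential."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, batch_norm2d, conv2d, relu

__all__ = ["Module", "Conv2d", "BatchNorm2d", "ReLU", "Sequential"]


class Module:
    """Base class with named parameters, buffers, submodules and train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(value, dtype=np.float32), requires_grad=True)
        self._params[name] = t
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.asarray(value, dtype=np.float32)
        self._buffers[name] = arr
        return arr

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (prefix + name if not prefix else f"{prefix}.{name}"), p
        for mname, mod in self._modules.items():
            sub = mname if not prefix else f"{prefix}.{mname}"
            yield from mod.named_parameters(sub)

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield (prefix + name if not prefix else f"{prefix}.{name}"), (self, name)
        for mname, mod in self._modules.items():
            sub = mname if not prefix else f"{prefix}.{mname}"
            yield from mod.named_buffers(sub)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for mod in self._modules.values():
            yield from mod.modules()

    def train(self, mode: bool = True):
        for mod in self.modules():
            mod.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    """Square-kernel 2-D convolution with He-normal initialization."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = self.register_parameter(
            "weight",
            rng.normal(0.0, std, size=(out_channels, in_channels, kernel_size, kernel_size)),
        )
        self.bias = self.register_parameter("bias", np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.padding)


class BatchNorm2d(Module):
    """Batch normalization; ``frozen_stats`` pins running statistics (used by
    transfer strategies so a retained stage cannot silently adapt)."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.frozen_stats = False
        self.gamma = self.register_parameter("gamma", np.ones(num_features))
        self.beta = self.register_parameter("beta", np.zeros(num_features))
        self.running_mean = self.register_buffer("running_mean", np.zeros(num_features))
        self.running_var = self.register_buffer("running_var", np.ones(num_features))

    def forward(self, x: Tensor) -> Tensor:
        training = self.training and not self.frozen_stats
        return batch_norm2d(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training=training,
            momentum=self.momentum,
            eps=self.eps,
        )


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self._seq = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def __iter__(self):
        return iter(self._seq)

    def __getitem__(self, i):
        return self._seq[i]

    def forward(self, x: Tensor) -> Tensor:
        for m in self._seq:
            x = m(x)
        return x
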