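"""Layer objects holding parameters for the autodiff ops."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Parameter, Tensor, add, conv2d, conv_transpose2x2

__all__ = ["Module", "Conv2d", "ConvTranspose2x2", "BatchNorm2d"]


class Module:
    """Base with recursive parameter discovery over attributes and lists."""

    training: bool = True

    def parameters(self) -> Iterator[Parameter]:
        for value in self.__dict__.values():
            yield from _params_of(value)

    def set_training(self, training: bool) -> None:
        self.training = training
        for value in self.__dict__.values():
            _set_training(value, training)


def _params_of(value) -> Iterator[Parameter]:
    if isinstance(value, Parameter):
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for item in value:
            yield from _params_of(item)


def _set_training(value, training: bool) -> None:
    if isinstance(value, Module):
        value.set_training(training)
    elif isinstance(value, (list, tuple)):
        for item in value:
            _set_training(item, training)


class Conv2d(Module):
    """Stride-1 convolution, He-initialized, optional bias (omit under BN)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng, bias: bool = False):
        if in_channels < 1 or out_channels < 1:
            raise ValueError(
                f"conv channels must be >= 1, got {in_channels} -> {out_channels} "
                f"(width configuration rounds to zero channels)"
            )
        self.kernel_size = kernel_size
        self.pad = kernel_size // 2
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = conv2d(x, self.weight, pad=self.pad)
        if self.bias is None:
            return out
        b = self.bias
        out_data = out.data + b.data[None, :, None, None]

        def backward(g):
            if b.requires_grad:
                b.accumulate(g.sum(axis=(0, 2, 3)))
            out.accumulate(g)

        return Tensor(out_data, _parents=(out, b), _backward=backward)


class ConvTranspose2x2(Module):
    """Kernel-2 stride-2 transposed convolution (2x upsampling)."""

    def __init__(self, in_channels: int, out_channels: int, rng):
        if in_channels < 1 or out_channels < 1:
            raise ValueError(f"conv channels must be >= 1, got {in_channels} -> {out_channels}")
        std = np.sqrt(2.0 / in_channels)
        self.weight = Parameter(rng.normal(0.0, std, (in_channels, out_channels, 2, 2)))

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2x2(x, self.weight)


class BatchNorm2d(Module):
    """Per-channel batchnorm with running statistics for eval mode."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        gamma, beta = self.gamma, self.beta
        if self.training:
            axes = (0, 2, 3)
            mean = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        training = self.training

        def backward(g):
            dbeta = g.sum(axis=(0, 2, 3))
            dgamma = (g * xhat).sum(axis=(0, 2, 3))
            if gamma.requires_grad:
                gamma.accumulate(dgamma)
            if beta.requires_grad:
                beta.accumulate(dbeta)
            if x.requires_grad:
                gscale = (gamma.data * inv_std)[None, :, None, None]
                if training:
                    gx = gscale * (
                        g
                        - dbeta[None, :, None, None] / m
                        - xhat * dgamma[None, :, None, None] / m
                    )
                else:
                    gx = gscale * g
                x.accumulate(gx.astype(np.float32))

        return Tensor(out_data, _parents=(x, gamma, beta), _backward=backward)
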