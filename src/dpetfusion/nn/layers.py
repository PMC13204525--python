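"""Parameterized layers on top of the autograd core."""

from __future__ import annotations

import numpy as np

from dpetfusion.nn import autograd as ag
from dpetfusion.nn.autograd import Tensor


class Module:
    """Base class: parameter discovery, train/eval mode, state export."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for value in vars(self).values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def set_training(self, training: bool) -> None:
        for m in self.modules():
            m.training = training

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        """All parameters plus buffers (for checksums / persistence)."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm3d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    training: bool = True


class Linear(Module):
    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        zero_init: bool = False,
        bias: bool = True,
    ):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = ag.matmul(x, self.w)
        return out + self.b if self.b is not None else out


class Conv3d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        kernel: int = 3,
        stride: int = 1,
        padding: int = 1,
        bias: bool = False,
    ):
        fan_in = c_in * kernel**3
        self.w = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel, kernel)),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(c_out), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv3d(x, self.w, self.b, self.stride, self.padding)


class BatchNorm3d(Module):
    """Channel batch normalization with running statistics for eval mode."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        shape = (1, -1, 1, 1, 1)
        if self.training:
            axes = (0, 2, 3, 4)
            mean = x.mean(axis=axes, keepdims=True)
            centered = x - mean
            var = ag.tmean(ag.pow_const(centered, 2.0), axis=axes, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mean.data.ravel()
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var.data.ravel()
            ).astype(np.float32)
            inv = ag.pow_const(var + Tensor(np.full(var.shape, self.eps)), -0.5)
            xhat = ag.mul(centered, inv)
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = ag.mul(
                x + Tensor(-self.running_mean.reshape(shape)),
                Tensor(inv.reshape(shape)),
            )
        return ag.mul(xhat, self.gamma.reshape(*shape)) + self.beta.reshape(*shape)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        centered = x - mean
        var = ag.tmean(ag.pow_const(centered, 2.0), axis=-1, keepdims=True)
        inv = ag.pow_const(var + Tensor(np.full(var.shape, self.eps)), -0.5)
        return ag.mul(ag.mul(centered, inv), self.gamma) + self.beta


class Adam:
    """Adam with decoupled weight decay (AdamW when ``weight_decay`` > 0)."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas=(0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
        lr_scales: list[float] | None = None,
    ):
        self.params = params
        self.lr = lr
        self.lr_scales = lr_scales if lr_scales is not None else [1.0] * len(params)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            lr_i = self.lr * self.lr_scales[i]
            update = lr_i * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay > 0:
                update = update + lr_i * self.weight_decay * p.data
            p.data -= update.astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
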