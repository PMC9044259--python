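"""Neural-network building blocks on top of the autodiff engine.

Mirrors the familiar Module/Parameter idiom: submodules and parameters are
registered automatically on attribute assignment, ``state_dict`` gives a
flat name->array mapping for checkpointing, and ``train()/eval()`` toggle
batch-norm behaviour.
"""

from __future__ import annotations

import math
from collections import OrderedDict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, array):
        self._buffers[name] = np.asarray(array, dtype=np.float32)
        object.__setattr__(self, name, self._buffers[name])

    def _set_buffer(self, name, array):
        """Replace a registered buffer (keeps the registry in sync)."""
        self._buffers[name] = array
        object.__setattr__(self, name, array)

    # -- traversal ----------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, mod in self._modules.items():
            yield from mod.named_parameters(prefix + mname + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name in self._buffers:
            yield prefix + name, self._buffers[name]
        for mname, mod in self._modules.items():
            yield from mod.named_buffers(prefix + mname + ".")

    def modules(self):
        yield self
        for mod in self._modules.values():
            yield from mod.modules()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    # -- serialization ------------------------------------------------------
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        bufs = {}

        def collect(mod, prefix):
            for bname in mod._buffers:
                bufs[prefix + bname] = (mod, bname)
            for mname, sub in mod._modules.items():
                collect(sub, prefix + mname + ".")

        collect(self, "")
        for name, arr in state.items():
            if name in own:
                if own[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                own[name].data = np.asarray(arr, dtype=np.float32).copy()
            elif name in bufs:
                mod, bname = bufs[name]
                mod._set_buffer(bname, np.asarray(arr, dtype=np.float32).copy())
            else:
                raise KeyError(f"unexpected entry {name!r} in state dict")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._seq = []
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
            self._seq.append(m)

    def forward(self, x):
        for m in self._seq:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self._seq)


class Conv2d(Module):
    """Grouped 2-D convolution with Kaiming-uniform initialisation."""

    def __init__(self, in_channels, out_channels, kernel_size,
                 stride: int = 1, padding: int | None = None,
                 groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("groups must divide both channel counts")
        k = int(kernel_size)
        self.stride = int(stride)
        self.padding = k // 2 if padding is None else int(padding)
        self.groups = int(groups)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = k
        rng = rng or np.random.default_rng()
        fan_in = (in_channels // groups) * k * k
        bound = math.sqrt(6.0 / fan_in)
        self.weight = Parameter(rng.uniform(
            -bound, bound, size=(out_channels, in_channels // groups, k, k)))
        if bias:
            bb = 1.0 / math.sqrt(fan_in)
            self.bias = Parameter(rng.uniform(-bb, bb, size=(out_channels,)))
        else:
            self.bias = None

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding,
                         groups=self.groups)


class BatchNorm2d(Module):
    """Standard batch normalisation over (N, H, W) with running statistics."""

    def __init__(self, num_features, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))

    def forward(self, x):
        c = self.num_features
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            centred = x - mean
            var = (centred * centred).mean(axis=(0, 2, 3), keepdims=True)
            inv = (var + self.eps) ** -0.5
            xhat = centred * inv
            m = self.momentum
            self._set_buffer("running_mean", (1 - m) * self.running_mean
                             + m * mean.data.reshape(c))
            self._set_buffer("running_var", (1 - m) * self.running_var
                             + m * var.data.reshape(c))
        else:
            mean = self.running_mean.reshape(1, c, 1, 1)
            inv = 1.0 / np.sqrt(self.running_var.reshape(1, c, 1, 1) + self.eps)
            xhat = (x - mean) * inv
        return self._affine(xhat)

    def _affine(self, xhat):
        c = self.num_features
        w = ad.reshape(self.weight, (1, c, 1, 1))
        b = ad.reshape(self.bias, (1, c, 1, 1))
        return xhat * w + b


class Adam:
    """Adam optimiser with optional decoupled-style L2 weight decay."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            mhat = self._m[i] / (1 - b1 ** self.t)
            vhat = self._v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
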