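"""Neural-network layers, losses and the AdamW optimizer on the autodiff core.

Layers follow the familiar Module pattern: parameters are discovered by
attribute traversal, `train()`/`eval()` toggle batch-norm statistics, and
convolution/linear layers can report multiply-accumulate counts into a
counter installed by the budget accountant (see `zoo.count_macs`).
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concat, conv2d, max_pool2d

# When not None, every Conv2d/Linear forward appends (name, macs) here.
_MAC_COUNTER: list | None = None


class Module:
    """Base class: children/parameter traversal and train/eval mode."""

    def __init__(self):
        self.training = True

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)

    def children(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for u in v:
                    if isinstance(u, Module):
                        yield u

    def modules(self):
        yield self
        for c in self.children():
            yield from c.modules()

    def parameters(self):
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    yield v

    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for k, v in self.__dict__.items():
            kids = []
            if isinstance(v, Module):
                kids = [(k, v)]
            elif isinstance(v, (list, tuple)):
                kids = [(f"{k}.{i}", u) for i, u in enumerate(v) if isinstance(u, Module)]
            for name, child in kids:
                sub = f"{prefix}.{name}" if prefix else name
                yield from child.named_modules(sub)

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self):
        out = {}
        for name, m in self.named_modules():
            for k, v in m.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad:
                    out[f"{name}.{k}" if name else k] = v.data.copy()
                elif isinstance(v, np.ndarray):
                    out[f"{name}.{k}" if name else k] = v.copy()
        return out

    def load_state_dict(self, sd: dict):
        for name, m in self.named_modules():
            for k, v in m.__dict__.items():
                key = f"{name}.{k}" if name else k
                if key in sd:
                    if isinstance(v, Tensor):
                        v.data = sd[key].astype(v.data.dtype).reshape(v.data.shape)
                    elif isinstance(v, np.ndarray):
                        m.__dict__[k] = sd[key].astype(v.dtype).reshape(v.shape)


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = math.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: int = 0, groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (c_in // groups) * kernel * kernel
        self.weight = Tensor(kaiming_uniform(rng, (c_out, c_in // groups, kernel, kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        y = conv2d(x, self.weight, self.bias, stride=self.stride,
                   padding=self.padding, groups=self.groups)
        if _MAC_COUNTER is not None:
            co, cg, kh, kw = self.weight.data.shape
            n, _, ho, wo = y.data.shape
            _MAC_COUNTER.append(("conv", n * co * cg * kh * kw * ho * wo))
            _MAC_COUNTER.append(("bias", y.data.size))
        return y


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(kaiming_uniform(rng, (d_in, d_out), d_in), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        if _MAC_COUNTER is not None:
            _MAC_COUNTER.append(("linear", x.data.shape[0] * self.weight.data.size))
            _MAC_COUNTER.append(("bias", y.data.size))
        return y


class BatchNorm2d(Module):
    """Batch statistics while training, running statistics at inference.

    eps 1e-5 and momentum 0.1 (fraction of the new batch statistic folded
    into the running estimate per step).
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x):
        if _MAC_COUNTER is not None:
            _MAC_COUNTER.append(("bn", 2 * x.data.size))
        axes = (0, 2, 3)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self.running_mean += self.momentum * (mu.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (unbiased - self.running_var)
            inv = (var + self.eps) ** -0.5
            xhat = xc * inv
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            inv = 1.0 / np.sqrt(self.running_var.reshape(1, -1, 1, 1) + self.eps)
            xhat = (x - Tensor(mu)) * Tensor(inv)
        c = self.weight.data.size
        return xhat * self.weight.reshape(1, c, 1, 1) + self.bias.reshape(1, c, 1, 1)


def _count_act(x):
    if _MAC_COUNTER is not None:
        _MAC_COUNTER.append(("act", x.data.size))


class ReLU(Module):
    def forward(self, x):
        _count_act(x)
        return x.relu()


class ReLU6(Module):
    def forward(self, x):
        _count_act(x)
        return x.clamp(0.0, 6.0)


class HSwish(Module):
    """x * relu6(x + 3) / 6 — the MobileNetV3 hard-swish."""

    def forward(self, x):
        _count_act(x)
        return x * ((x + 3.0).clamp(0.0, 6.0) * (1.0 / 6.0))


class SiLU(Module):
    def forward(self, x):
        _count_act(x)
        return x * x.sigmoid()


class Sigmoid(Module):
    def forward(self, x):
        _count_act(x)
        return x.sigmoid()


class Identity(Module):
    def forward(self, x):
        return x


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        if _MAC_COUNTER is not None:
            _MAC_COUNTER.append(("pool", x.data.size))
        return max_pool2d(x, self.kernel, self.stride, self.padding)


class GlobalAvgPool(Module):
    """Adaptive average pooling to 1x1, keeping NCHW."""

    def forward(self, x):
        if _MAC_COUNTER is not None:
            _MAC_COUNTER.append(("pool", x.data.size))
        return x.mean(axis=(2, 3), keepdims=True)


class Flatten(Module):
    def forward(self, x):
        return x.reshape(x.data.shape[0], -1)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for l in self.layers:
            x = l(x)
        return x


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; labels are integer class ids."""
    n = logits.data.shape[0]
    zmax = Tensor(logits.data.max(axis=1, keepdims=True))  # constant shift for stability
    z = logits - zmax
    logsumexp = z.exp().sum(axis=1, keepdims=True).log()
    picked = z[np.arange(n), labels].reshape(n, 1)
    return (logsumexp - picked).mean()


class AdamW:
    """Decoupled weight decay Adam (lr 1e-4, wd 1e-2 defaults)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            mhat = m / bc1
            vhat = v / bc2
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
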