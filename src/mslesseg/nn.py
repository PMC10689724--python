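"""Minimal NumPy automatic-differentiation engine for 2D segmentation nets.

Implements exactly the operations the multi-branch U-Net needs — 2D
convolution ('same' padding), batch normalization, 2x2 max-pooling, 2x
nearest-neighbour upsampling, channel concatenation, ReLU and sigmoid —
as a define-by-run tape over float32 ndarrays, plus Glorot-normal
initialization and the Adam optimizer.  Convolutions are evaluated as
one BLAS GEMM per kernel tap over shifted views, which keeps desk-scale
training of reduced-width models practical on one CPU.

Array layout is (N, C, H, W) throughout.
"""

from __future__ import annotations

import contextlib

import numpy as np



_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode): ops return plain
    tensors without parents or backward rules, so intermediate
    activations are freed as soon as they go out of scope."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _attach(res, backward):
    if _grad_enabled:
        res._backward = backward


class Tensor:
    """A node on the autodiff tape: value, gradient and backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        if not _grad_enabled:
            parents = ()
            backward = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None):
        """Reverse-mode sweep from this (scalar) tensor."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float32)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accumulate(self, grad):
        g = np.asarray(grad, dtype=np.float32)
        self.grad = g if self.grad is None else self.grad + g


def _same_pad(k: int) -> tuple[int, int]:
    before = (k - 1) // 2
    return before, k - 1 - before


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """'same'-padded 2D convolution; w has shape (C_out, C_in, k, k).

    Evaluated as k*k shifted GEMMs (one per kernel tap), which keeps the
    working set small and feeds BLAS contiguous operands.
    """
    co, ci, k, _ = w.shape
    n, _, h, wd = x.shape
    pb, pa = _same_pad(k)
    if k == 1:
        xp = x.data
    else:
        xp = np.pad(x.data, ((0, 0), (0, 0), (pb, pa), (pb, pa)))
    out = np.zeros((n, co, h * wd), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            xs = np.ascontiguousarray(
                xp[:, :, i : i + h, j : j + wd]
            ).reshape(n, ci, h * wd)
            out += w.data[:, :, i, j] @ xs
    out = out.reshape(n, co, h, wd)
    if b is not None:
        out += b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)
    res = Tensor(out, parents=parents)

    def backward(grad):
        grad2 = grad.reshape(n, co, h * wd)
        if w.requires_grad:
            # dW[o,c,i,j] = sum_nhw x_pad[n,c,h+i,w+j] * grad[n,o,h,w]
            dw = np.empty_like(w.data)
            for i in range(k):
                for j in range(k):
                    xs = np.ascontiguousarray(
                        xp[:, :, i : i + h, j : j + wd]
                    ).reshape(n, ci, h * wd)
                    dw[:, :, i, j] = np.matmul(
                        grad2, xs.transpose(0, 2, 1)
                    ).sum(axis=0)
            w._accumulate(dw)
        if b is not None and b.requires_grad:
            b._accumulate(grad.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            if k == 1:
                dx = (w.data[:, :, 0, 0].T @ grad2).reshape(n, ci, h, wd)
                x._accumulate(dx)
            else:
                dxp = np.zeros_like(xp)
                for i in range(k):
                    for j in range(k):
                        contrib = (w.data[:, :, i, j].T @ grad2).reshape(
                            n, ci, h, wd
                        )
                        dxp[:, :, i : i + h, j : j + wd] += contrib
                x._accumulate(dxp[:, :, pb : pb + h, pb : pb + wd])

    _attach(res, backward)
    return res


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max-pooling with stride 2 (spatial dims must be even)."""
    n, c, h, w = x.shape
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out = blocks.max(axis=(3, 5))
    res = Tensor(out, parents=(x,))

    def backward(grad):
        mask = blocks == out[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)
        g = mask * (grad[:, :, :, None, :, None] / counts)
        x._accumulate(g.reshape(n, c, h, w))

    _attach(res, backward)
    return res


def upsample2d(x: Tensor) -> Tensor:
    """2x nearest-neighbour upsampling."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)
    res = Tensor(out, parents=(x,))

    def backward(grad):
        n, c, h2, w2 = grad.shape
        x._accumulate(
            grad.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
        )

    _attach(res, backward)
    return res


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the channel axis."""
    out = np.concatenate([t.data for t in tensors], axis=1)
    res = Tensor(out, parents=tuple(tensors))

    def backward(grad):
        ofs = 0
        for t in tensors:
            c = t.shape[1]
            if t.requires_grad:
                t._accumulate(grad[:, ofs : ofs + c])
            ofs += c

    _attach(res, backward)
    return res


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0.0)
    res = Tensor(out, parents=(x,))

    def backward(grad):
        x._accumulate(grad * (x.data > 0))

    _attach(res, backward)
    return res


def sigmoid(x: Tensor) -> Tensor:
    d = x.data
    out = np.empty_like(d)
    pos = d >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    e = np.exp(d[~pos])
    out[~pos] = e / (1.0 + e)
    res = Tensor(out, parents=(x,))

    def backward(grad):
        x._accumulate(grad * out * (1.0 - out))

    _attach(res, backward)
    return res


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: tracks parameters, buffers and train/eval mode."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix=""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield f"{prefix}{name}", val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(
                            f"{prefix}{name}.{i}."
                        )

    def named_buffers(self, prefix=""):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield from val.named_buffers(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{name}.{i}.")
            elif name.startswith("buf_"):
                yield f"{prefix}{name}", val

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for val in vars(self).items():
            pass
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({k: np.array(v) for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        for k, v in state.items():
            if k in params:
                if params[k].data.shape != v.shape:
                    raise ValueError(
                        f"shape mismatch for {k}: "
                        f"{params[k].data.shape} vs {v.shape}"
                    )
                params[k].data = v.astype(np.float32).copy()
        bufs = dict(self._buffer_owners())
        for k, v in state.items():
            if k in bufs:
                owner, attr = bufs[k]
                setattr(owner, attr, v.astype(np.float32).copy())

    def _buffer_owners(self, prefix=""):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield from val._buffer_owners(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item._buffer_owners(f"{prefix}{name}.{i}.")
            elif name.startswith("buf_"):
                yield f"{prefix}{name}", (self, name)


def glorot_normal(rng: np.random.Generator, shape, fan_in, fan_out):
    sd = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, sd, size=shape).astype(np.float32)


class Conv2D(Module):
    """'same' 2D convolution with optional bias, Glorot-normal init."""

    def __init__(self, cin, cout, k, rng, bias=True):
        super().__init__()
        self.weight = Parameter(
            glorot_normal(rng, (cout, cin, k, k), cin * k * k, cout * k * k)
        )
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)

    def n_params(self):
        n = self.weight.data.size
        if self.bias is not None:
            n += self.bias.data.size
        return n


class BatchNorm2D(Module):
    """Per-channel batch normalization with moving statistics.

    gamma/beta are trainable; the moving mean and variance (``buf_*``)
    are the non-trainable state.
    """

    def __init__(self, c, momentum=0.9, eps=1e-3):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.buf_moving_mean = np.zeros(c, dtype=np.float32)
        self.buf_moving_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            m = self.momentum
            self.buf_moving_mean = (
                m * self.buf_moving_mean + (1 - m) * mean
            ).astype(np.float32)
            self.buf_moving_var = (
                m * self.buf_moving_var + (1 - m) * var
            ).astype(np.float32)
        else:
            mean = self.buf_moving_mean
            var = self.buf_moving_var

        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xc = x.data - mean[None, :, None, None]
        xhat = xc * inv_sd[None, :, None, None]
        out = (
            self.gamma.data[None, :, None, None] * xhat
            + self.beta.data[None, :, None, None]
        )
        res = Tensor(out.astype(np.float32), parents=(x, self.gamma, self.beta))
        training = self.training

        def backward(grad):
            if self.gamma.requires_grad:
                self.gamma._accumulate((grad * xhat).sum(axis=(0, 2, 3)))
            if self.beta.requires_grad:
                self.beta._accumulate(grad.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                g = self.gamma.data[None, :, None, None]
                if training:
                    mcount = grad.shape[0] * grad.shape[2] * grad.shape[3]
                    dxhat = grad * g
                    isd = inv_sd[None, :, None, None]
                    sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
                    sum_dxhat_xhat = (dxhat * xhat).sum(
                        axis=(0, 2, 3), keepdims=True
                    )
                    dx = (
                        isd
                        / mcount
                        * (mcount * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)
                    )
                else:
                    dx = grad * g * inv_sd[None, :, None, None]
                x._accumulate(dx.astype(np.float32))

        _attach(res, backward)
        return res

    def n_params(self):
        return 2 * self.gamma.data.size  # trainable gamma+beta

    def n_non_trainable(self):
        return self.buf_moving_mean.size + self.buf_moving_var.size


class Adam:
    """Adam optimizer with externally scheduled learning rate."""

    def __init__(self, params, lr=3e-4, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
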