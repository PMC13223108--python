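"""Reverse-mode automatic differentiation on NumPy arrays.

A compact tape-free autodiff engine built for one purpose: training
spectrogram classifiers whose loss contains an input-gradient term.  The
attribution-alignment objective penalizes a function of ``dlogit/dinput``,
so the training gradient needs *second-order* derivatives (double
backpropagation).  Every primitive therefore expresses its vector-Jacobian
product in terms of other primitives: calling :func:`grad` with
``create_graph=True`` yields gradients that are themselves differentiable
graph nodes.

Conventions
-----------
* all data are float64 ndarrays;
* ``|x|`` uses the subgradient 0 at x = 0 (its vjp multiplies by sign(x));
* ``relu`` and ``max`` treat their selection masks as constants, so second
  derivatives through them are zero almost everywhere, as expected.

The layer/optimizer section at the bottom mirrors the familiar
``Module``/``Parameter`` idiom at the minimal scale this package needs.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

# --------------------------------------------------------------------------
# Tensor and graph machinery
# --------------------------------------------------------------------------

_GRAD_ENABLED = True
_DEFAULT_DTYPE = np.float64


class default_dtype:
    """Context manager setting the dtype of newly created tensors.

    Training runs in float32 (standard practice, ~2x faster on CPU BLAS);
    float64 remains the global default so evaluation-time arithmetic and
    oracle comparisons keep full precision.
    """

    def __init__(self, dtype):
        self.dtype = np.dtype(dtype)

    def __enter__(self):
        global _DEFAULT_DTYPE
        self._prev = _DEFAULT_DTYPE
        _DEFAULT_DTYPE = self.dtype
        return self

    def __exit__(self, *exc):
        global _DEFAULT_DTYPE
        _DEFAULT_DTYPE = self._prev
        return False


class no_grad:
    """Context manager disabling graph construction (evaluation mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    __slots__ = ("data", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False, parents=(), vjp=None):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._vjp = vjp

    # -- introspection ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, astensor(other))

    def __radd__(self, other):
        return add(astensor(other), self)

    def __sub__(self, other):
        return sub(self, astensor(other))

    def __rsub__(self, other):
        return sub(astensor(other), self)

    def __mul__(self, other):
        return mul(self, astensor(other))

    def __rmul__(self, other):
        return mul(astensor(other), self)

    def __truediv__(self, other):
        return div(self, astensor(other))

    def __rtruediv__(self, other):
        return div(astensor(other), self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, astensor(other))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: tuple, vjp: Callable) -> Tensor:
    """Create a graph node; constant-folds when grad is off or no parent needs it."""
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        return Tensor(data, True, parents, vjp)
    return Tensor(data)


def grad(output: Tensor, inputs: Sequence[Tensor], create_graph: bool = False):
    """Gradients of a scalar ``output`` w.r.t. ``inputs``.

    With ``create_graph=True`` the returned tensors carry their own graph,
    so a further :func:`grad` call differentiates through them.
    """
    if output.size != 1:
        raise ValueError("grad expects a scalar output")
    # post-order over the subgraph that requires grad (parents before node)
    topo: list[Tensor] = []
    visited: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(output, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            topo.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in visited:
                stack.append((p, False))

    ctx = no_grad() if not create_graph else _nullcontext()
    grads: dict[int, Tensor] = {id(output): Tensor(np.ones_like(output.data))}
    with ctx:
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if any(node is inp for inp in inputs):
                grads[id(node)] = g  # keep for the caller
            if node._vjp is None:
                continue
            parent_grads = node._vjp(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                acc = grads.get(id(p))
                grads[id(p)] = pg if acc is None else add(acc, pg)
        out = []
        for inp in inputs:
            g = grads.get(id(inp))
            if g is None:
                g = Tensor(np.zeros_like(inp.data))
            out.append(g if create_graph else g.detach())
    return out


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False


# --------------------------------------------------------------------------
# Primitives.  Each vjp is written with Tensor ops so grads are differentiable.
# --------------------------------------------------------------------------


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Sum ``g`` down to ``shape`` (the adjoint of NumPy broadcasting)."""
    if g.shape == shape:
        return g
    ndiff = g.ndim - len(shape)
    if ndiff > 0:
        g = tsum(g, axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return reshape(g, shape)


def add(a: Tensor, b: Tensor) -> Tensor:
    return _node(a.data + b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))


def sub(a: Tensor, b: Tensor) -> Tensor:
    return _node(a.data - b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.shape),
                            _unbroadcast(neg(g), b.shape)))


def neg(a: Tensor) -> Tensor:
    return _node(-a.data, (a,), lambda g: (neg(g),))


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _node(a.data * b.data, (a, b),
                 lambda g: (_unbroadcast(mul(g, b), a.shape),
                            _unbroadcast(mul(g, a), b.shape)))


def div(a: Tensor, b: Tensor) -> Tensor:
    return mul(a, power(b, -1.0))


def power(a: Tensor, p: float) -> Tensor:
    p = float(p)
    return _node(a.data ** p, (a,),
                 lambda g: (mul(g, mul(Tensor(np.full((), p)), power(a, p - 1.0))),))


def texp(a: Tensor) -> Tensor:
    # the vjp rebuilds exp(a) rather than closing over the output tensor:
    # a self-reference would create a cycle that delays freeing the graph
    return _node(np.exp(a.data), (a,), lambda g: (mul(g, texp(a)),))


def tlog(a: Tensor) -> Tensor:
    return _node(np.log(a.data), (a,), lambda g: (div(g, a),))


def tsqrt(a: Tensor) -> Tensor:
    return power(a, 0.5)


def tabs(a: Tensor) -> Tensor:
    sign = Tensor(np.sign(a.data))  # constant: subgradient 0 at 0
    return _node(np.abs(a.data), (a,), lambda g: (mul(g, sign),))


def relu(a: Tensor) -> Tensor:
    mask = Tensor((a.data > 0).astype(np.float64))
    return _node(a.data * mask.data, (a,), lambda g: (mul(g, mask),))


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    axis_t = axis if axis is None else (axis if isinstance(axis, tuple) else (axis,))

    def vjp(g: Tensor):
        if axis_t is None:
            shp = (1,) * a.ndim
        elif keepdims:
            shp = g.shape
        else:
            shp = list(a.shape)
            for ax in sorted(ax % a.ndim for ax in axis_t):
                shp[ax] = 1
            shp = tuple(shp)
        return (broadcast_to(reshape(g, shp), a.shape),)

    return _node(np.sum(a.data, axis=axis_t, keepdims=keepdims), (a,), vjp)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


def broadcast_to(a: Tensor, shape: tuple) -> Tensor:
    return _node(np.broadcast_to(a.data, shape).copy(), (a,),
                 lambda g: (_unbroadcast(g, a.shape),))


def reshape(a: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    return _node(a.data.reshape(shape), (a,),
                 lambda g: (reshape(g, a.shape),))


def transpose(a: Tensor, axes: tuple) -> Tensor:
    inv = tuple(np.argsort(axes))
    return _node(np.transpose(a.data, axes), (a,),
                 lambda g: (transpose(g, inv),))


def swap_last2(a: Tensor) -> Tensor:
    axes = tuple(range(a.ndim - 2)) + (a.ndim - 1, a.ndim - 2)
    return transpose(a, axes)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def vjp(g: Tensor):
        ga = matmul(g, swap_last2(b))
        gb = matmul(swap_last2(a), g)
        return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

    return _node(np.matmul(a.data, b.data), (a, b), vjp)


def take_along_rows(a: Tensor, cols: np.ndarray) -> Tensor:
    """out[i] = a[i, cols[i]] for a 2-D tensor (used for true-class scores)."""
    cols = np.asarray(cols, dtype=np.intp)
    rows = np.arange(a.shape[0])
    return _node(a.data[rows, cols], (a,),
                 lambda g: (put_along_rows(g, cols, a.shape),))


def put_along_rows(g: Tensor, cols: np.ndarray, shape: tuple) -> Tensor:
    cols = np.asarray(cols, dtype=np.intp)
    rows = np.arange(shape[0])
    out = np.zeros(shape)
    np.add.at(out, (rows, cols), g.data)
    return _node(out, (g,), lambda gg: (take_along_rows(gg, cols),))


def gather_cols(a: Tensor, idx: np.ndarray) -> Tensor:
    """out[..., j] = a[..., idx[j]] along the last axis (im2col gather)."""
    idx = np.asarray(idx, dtype=np.intp)
    n = a.shape[-1]
    return _node(a.data[..., idx], (a,),
                 lambda g: (scatter_cols(g, idx, n),))


def scatter_cols(g: Tensor, idx: np.ndarray, n: int) -> Tensor:
    """Adjoint of :func:`gather_cols`: scatter-add along the last axis.

    Duplicate indices accumulate, which is exactly the adjoint of a gather
    that reads a position several times (overlapping convolution patches).
    """
    idx = np.asarray(idx, dtype=np.intp)
    gflat = g.data.reshape(-1, g.shape[-1])
    rows = [np.bincount(idx, weights=gflat[b], minlength=n)
            for b in range(gflat.shape[0])]
    out = np.stack(rows).reshape(g.shape[:-1] + (n,))
    return _node(out, (g,), lambda gg: (gather_cols(gg, idx),))


def pad_axis(a: Tensor, axis: int, before: int, after: int) -> Tensor:
    pads = [(0, 0)] * a.ndim
    pads[axis] = (before, after)
    return _node(np.pad(a.data, pads), (a,),
                 lambda g: (narrow(g, axis, before, a.shape[axis]),))


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    sl = [slice(None)] * a.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)
    after = a.shape[axis] - start - length
    return _node(a.data[sl], (a,),
                 lambda g: (pad_axis(g, axis, start, after),))


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def vjp(g: Tensor):
        return tuple(narrow(g, axis, int(offsets[i]), sizes[i])
                     for i in range(len(tensors)))

    return _node(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), vjp)


def tmax(a: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Max along one axis; ties resolve to the first index (deterministic)."""
    am = np.argmax(a.data, axis=axis)
    onehot = np.zeros_like(a.data)
    np.put_along_axis(onehot, np.expand_dims(am, axis), 1.0, axis=axis)
    mask = Tensor(onehot)

    def vjp(g: Tensor):
        shp = list(a.shape)
        shp[axis] = 1
        g = g if keepdims else reshape(g, tuple(shp))
        return (mul(broadcast_to(g, a.shape), mask),)

    return _node(np.max(a.data, axis=axis, keepdims=keepdims), (a,), vjp)


# --------------------------------------------------------------------------
# Neural-network building blocks (convolution via differentiable im2col)
# --------------------------------------------------------------------------


from functools import lru_cache


@lru_cache(maxsize=256)
def _im2col_indices(C, H, W, kh, kw, sh, sw):
    OH = (H - kh) // sh + 1
    OW = (W - kw) // sw + 1
    c = np.repeat(np.arange(C), kh * kw)
    ki = np.tile(np.repeat(np.arange(kh), kw), C)
    kj = np.tile(np.arange(kw), kh * C)
    oi = np.repeat(np.arange(OH) * sh, OW)
    oj = np.tile(np.arange(OW) * sw, OH)
    # rows: (C*kh*kw, 1); cols: (1, OH*OW)
    rows_i = ki[:, None] + oi[None, :]
    rows_j = kj[:, None] + oj[None, :]
    flat = (c[:, None] * H + rows_i) * W + rows_j
    return flat.ravel(), OH, OW


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=(1, 1), padding=(0, 0), depthwise: bool = False) -> Tensor:
    """2-D convolution (cross-correlation) over (B, C, H, W) inputs."""
    B, C, H, W = x.shape
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    if ph or pw:
        x = pad_axis(pad_axis(x, 2, ph, ph), 3, pw, pw)
        H, W = H + 2 * ph, W + 2 * pw
    if depthwise:
        Cmul, _, kh, kw = w.shape  # (C, 1, kh, kw)
        idx, OH, OW = _im2col_indices(C, H, W, kh, kw, sh, sw)
        patches = gather_cols(reshape(x, (B, C * H * W)), idx)
        patches = reshape(patches, (B, C, kh * kw, OH * OW))
        wr = reshape(w, (1, C, kh * kw, 1))
        out = tsum(mul(patches, wr), axis=2)  # (B, C, OH*OW)
        out = reshape(out, (B, C, OH, OW))
        Cout = C
    else:
        Cout, Cin, kh, kw = w.shape
        if Cin != C:
            raise ValueError(f"conv2d: expected {Cin} input channels, got {C}")
        idx, OH, OW = _im2col_indices(C, H, W, kh, kw, sh, sw)
        patches = gather_cols(reshape(x, (B, C * H * W)), idx)
        patches = reshape(patches, (B, C * kh * kw, OH * OW))
        wf = reshape(w, (Cout, C * kh * kw))
        out = matmul(wf, patches)  # (B, Cout, OH*OW) by broadcasting
        out = reshape(out, (B, Cout, OH, OW))
    if b is not None:
        out = add(out, reshape(b, (1, Cout, 1, 1)))
    return out


def max_pool2d(x: Tensor, kernel=2, stride=None, padding=0) -> Tensor:
    B, C, H, W = x.shape
    kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
    stride = kernel if stride is None else stride
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    if ph or pw:
        # zero-pad, then push the border to -1e30 so padding never wins the max
        x = pad_axis(pad_axis(x, 2, ph, ph), 3, pw, pw)
        border = np.full((1, 1, H + 2 * ph, W + 2 * pw), -1e30)
        border[:, :, ph:ph + H, pw:pw + W] = 0.0
        x = add(x, Tensor(border))
        H, W = H + 2 * ph, W + 2 * pw
    idx, OH, OW = _im2col_indices(C, H, W, kh, kw, sh, sw)
    patches = gather_cols(reshape(x, (B, C * H * W)), idx)
    patches = reshape(patches, (B, C, kh * kw, OH * OW))
    out = tmax(patches, axis=2)
    return reshape(out, (B, C, OH, OW))


def avg_pool2d(x: Tensor, kernel=2, stride=None) -> Tensor:
    B, C, H, W = x.shape
    kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
    stride = kernel if stride is None else stride
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    idx, OH, OW = _im2col_indices(C, H, W, kh, kw, sh, sw)
    patches = gather_cols(reshape(x, (B, C * H * W)), idx)
    patches = reshape(patches, (B, C, kh * kw, OH * OW))
    return reshape(tmean(patches, axis=2), (B, C, OH, OW))


def global_avg_pool(x: Tensor) -> Tensor:
    return tmean(x, axis=(2, 3))


def logsumexp_rows(z: Tensor) -> Tensor:
    m = Tensor(np.max(z.data, axis=1, keepdims=True))  # detached shift
    return add(tlog(tsum(texp(sub(z, m)), axis=1)), reshape(m, (z.shape[0],)))


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over the batch for integer labels."""
    labels = np.asarray(labels, dtype=np.intp)
    if logits.ndim != 2 or logits.shape[0] != labels.shape[0]:
        raise ValueError("cross_entropy: logits must be (B, C) matching labels")
    lse = logsumexp_rows(logits)
    zy = take_along_rows(logits, labels)
    return tmean(sub(lse, zy))


# --------------------------------------------------------------------------
# Modules, parameters, optimizer
# --------------------------------------------------------------------------


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal container with recursive parameter discovery and train/eval."""

    def __init__(self):
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def train(self):
        self.training = True
        for _, c in self._children():
            c.train()
        return self

    def eval(self):
        self.training = False
        for _, c in self._children():
            c.eval()
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        d.update({name: b.copy() for name, b in self.named_buffers()})
        return d

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def load_state_dict(self, d: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        buffers = {}
        for name, _ in self.named_buffers():
            buffers[name] = name
        for key, val in d.items():
            if key in params:
                params[key].data = np.asarray(val, dtype=np.float64).copy()
            else:
                self._set_buffer(key, np.asarray(val, dtype=np.float64).copy())
        return self

    def _set_buffer(self, dotted: str, value: np.ndarray):
        obj: object = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            if part.isdigit():
                obj = obj[int(part)]  # type: ignore[index]
            else:
                attr = getattr(obj, part)
                obj = attr
        setattr(obj, parts[-1], value)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (out_features, in_features)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_features))

    def forward(self, x: Tensor) -> Tensor:
        return add(matmul(x, transpose(self.weight, (1, 0))), self.bias)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 rng: np.random.Generator, stride=1, padding=0,
                 bias: bool = True, depthwise: bool = False):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        self.stride = (stride, stride) if isinstance(stride, int) else stride
        self.padding = (padding, padding) if isinstance(padding, int) else padding
        self.depthwise = depthwise
        fan_in = (1 if depthwise else in_channels) * kh * kw
        std = math.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        shape = (in_channels, 1, kh, kw) if depthwise else (out_channels, in_channels, kh, kw)
        self.weight = Parameter(rng.normal(0.0, std, shape))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding,
                      depthwise=self.depthwise)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        C = x.shape[1]
        if self.training:
            mu = tmean(x, axis=(0, 2, 3), keepdims=True)
            var = tmean(power(sub(x, mu), 2.0), axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(C))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(C))
        else:
            mu = Tensor(self.running_mean.reshape(1, C, 1, 1))
            var = Tensor(self.running_var.reshape(1, C, 1, 1))
        xhat = div(sub(x, mu), tsqrt(add(var, Tensor(self.eps))))
        return add(mul(xhat, reshape(self.gamma, (1, C, 1, 1))),
                   reshape(self.beta, (1, C, 1, 1)))


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay added to grads."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads: Sequence[Tensor]):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, (p, g) in enumerate(zip(self.params, grads)):
            gd = g.data if isinstance(g, Tensor) else np.asarray(g)
            if self.weight_decay:
                gd = gd + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * gd
            self.v[i] = b2 * self.v[i] + (1 - b2) * gd * gd
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
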