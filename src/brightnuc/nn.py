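"""Minimal reverse-mode automatic differentiation and CNN layers on numpy.

Implements exactly the operations the segmentation architectures in this
package need: 2-D convolution (stride 1, 'same' padding), transposed
convolution (stride 2), batch normalization, 2x2 max pooling, edge-clipped
average pooling, bilinear resizing, channel concatenation, residual
addition, ReLU/sigmoid, and binary cross-entropy, together with an Adam
optimizer.  Arrays are float32 in NCHW layout throughout.

The autodiff core is a define-by-run tape: every operation returns a
:class:`Node` that remembers its parents and a closure computing the local
vector-Jacobian products.  :func:`backward` walks the tape in reverse
topological order and accumulates gradients into leaf nodes (parameters).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


# ---------------------------------------------------------------------------
# autodiff core
# ---------------------------------------------------------------------------

class Node:
    """One value in the computation tape."""

    __slots__ = ("data", "parents", "grad_fn", "grad")

    def __init__(self, data, parents=(), grad_fn=None):
        self.data = np.asarray(data, dtype=F32)
        self.parents = parents
        self.grad_fn = grad_fn  # grad -> tuple of parent grads (or None)
        self.grad = None

    @property
    def shape(self):
        return self.data.shape


def as_node(x):
    return x if isinstance(x, Node) else Node(x)


def backward(root: Node, seed_grad=None):
    """Accumulate d(root)/d(leaf) into ``grad`` of every tape node."""
    topo, seen = [], set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))
    root.grad = (np.ones_like(root.data) if seed_grad is None
                 else np.asarray(seed_grad, dtype=F32))
    for node in reversed(topo):
        if node.grad_fn is None or node.grad is None:
            continue
        for parent, g in zip(node.parents, node.grad_fn(node.grad)):
            if g is None:
                continue
            if parent.grad is None:
                parent.grad = g
            else:
                parent.grad = parent.grad + g


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------

def add(a: Node, b: Node) -> Node:
    a, b = as_node(a), as_node(b)
    return Node(a.data + b.data, (a, b), lambda g: (g, g))


def relu(x: Node) -> Node:
    x = as_node(x)
    mask = x.data > 0
    return Node(x.data * mask, (x,), lambda g: (g * mask,))


def sigmoid(x: Node) -> Node:
    x = as_node(x)
    # numerically stable logistic
    out = np.empty_like(x.data)
    pos = x.data >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    ex = np.exp(x.data[~pos])
    out[~pos] = ex / (1.0 + ex)
    return Node(out, (x,), lambda g: (g * out * (1.0 - out),))


def concat(nodes, axis=1) -> Node:
    nodes = [as_node(n) for n in nodes]
    sizes = [n.data.shape[axis] for n in nodes]
    splits = np.cumsum(sizes)[:-1]

    def grad_fn(g):
        return tuple(np.split(g, splits, axis=axis))

    return Node(np.concatenate([n.data for n in nodes], axis=axis),
                tuple(nodes), grad_fn)


def _im2col(xp, kh, kw):
    # xp: padded (N, C, Hp, Wp) -> (N, Ho, Wo, C*kh*kw)
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,Ho,Wo,kh,kw
    n, c, ho, wo = win.shape[:4]
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n, ho, wo, c * kh * kw)


def conv2d(x: Node, w: Node, b: Node) -> Node:
    """Stride-1 'same' convolution.  w: (Cout, Cin, k, k), b: (Cout,)."""
    x, w, b = as_node(x), as_node(w), as_node(b)
    n, cin, h, wd = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    assert cin == cin_w, f"channel mismatch {cin} vs {cin_w}"
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = _im2col(xp, kh, kw)                     # N,H,W,Cin*k*k
    wf = w.data.reshape(cout, -1)                  # Cout, Cin*k*k
    y = cols @ wf.T + b.data                       # N,H,W,Cout
    y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def grad_fn(g):
        gf = g.transpose(0, 2, 3, 1)               # N,H,W,Cout
        db = gf.sum(axis=(0, 1, 2))
        gfm = gf.reshape(-1, cout)
        dw = (gfm.T @ cols.reshape(-1, cin * kh * kw)).reshape(w.data.shape)
        dcols = (gfm @ wf).reshape(n, h, wd, cin, kh, kw)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + h, j:j + wd] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        dx = dxp[:, :, ph:ph + h, pw:pw + wd] if (ph or pw) else dxp
        return dx, dw, db

    return Node(y, (x, w, b), grad_fn)


def conv_transpose2d(x: Node, w: Node, b: Node, stride: int = 2) -> Node:
    """Transposed convolution doubling spatial size.

    w: (Cin, Cout, k, k) with k in {2, 3}; output is (N, Cout, H*s, W*s)
    using padding k//2 and matching output padding.
    """
    x, w, b = as_node(x), as_node(w), as_node(b)
    n, cin, h, wd = x.data.shape
    cin_w, cout, kh, kw = w.data.shape
    assert cin == cin_w
    s = stride
    p = (kh - 1) // 2
    hf, wf_ = (h - 1) * s + kh, (wd - 1) * s + kw
    prod = (x.data.transpose(0, 2, 3, 1).reshape(-1, cin)
            @ w.data.reshape(cin, -1)).reshape(n, h, wd, cout, kh, kw)
    yf = np.zeros((n, cout, hf, wf_), dtype=F32)
    for i in range(kh):
        for j in range(kw):
            yf[:, :, i:i + (h - 1) * s + 1:s, j:j + (wd - 1) * s + 1:s] += \
                prod[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    ho, wo = h * s, wd * s
    y = yf[:, :, p:p + ho, p:p + wo] + b.data[None, :, None, None]

    def grad_fn(g):
        db = g.sum(axis=(0, 2, 3))
        gf = np.zeros((n, cout, hf, wf_), dtype=F32)
        gf[:, :, p:p + ho, p:p + wo] = g
        dprod = np.empty((n, h, wd, cout, kh, kw), dtype=F32)
        for i in range(kh):
            for j in range(kw):
                dprod[:, :, :, :, i, j] = gf[
                    :, :, i:i + (h - 1) * s + 1:s, j:j + (wd - 1) * s + 1:s
                ].transpose(0, 2, 3, 1)
        dpf = dprod.reshape(-1, cout * kh * kw)
        dx = (dpf @ w.data.reshape(cin, -1).T).reshape(n, h, wd, cin)
        dw = (x.data.transpose(0, 2, 3, 1).reshape(-1, cin).T @ dpf
              ).reshape(w.data.shape)
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2)), dw, db

    return Node(y, (x, w, b), grad_fn)


def maxpool2d(x: Node) -> Node:
    """2x2 max pooling, stride 2; H and W must be even."""
    x = as_node(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2d needs even spatial size, got {h}x{w}")
    win = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = win.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def grad_fn(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        return (dx,)

    return Node(y, (x,), grad_fn)


def avgpool2d(x: Node, pool: int) -> Node:
    """Average pooling with stride == pool and edge-clipped windows.

    Output size is ceil(H / pool); incomplete border windows average over
    the pixels they actually cover, so any spatial size is valid.
    """
    x = as_node(x)
    n, c, h, w = x.data.shape
    pool = min(pool, h, w)
    if pool == 1:
        return Node(x.data.copy(), (x,), lambda g: (g,))
    if h % pool == 0 and w % pool == 0:
        y = x.data.reshape(n, c, h // pool, pool, w // pool, pool).mean(axis=(3, 5))

        def grad_fn(g):
            dx = np.repeat(np.repeat(g, pool, axis=2), pool, axis=3) / (pool * pool)
            return (dx,)

        return Node(y, (x,), grad_fn)

    ho, wo = -(-h // pool), -(-w // pool)
    y = np.empty((n, c, ho, wo), dtype=F32)
    for i in range(ho):
        for j in range(wo):
            sl = x.data[:, :, i * pool:(i + 1) * pool, j * pool:(j + 1) * pool]
            y[:, :, i, j] = sl.mean(axis=(2, 3))

    def grad_fn(g):
        dx = np.zeros_like(x.data)
        for i in range(ho):
            for j in range(wo):
                win = dx[:, :, i * pool:(i + 1) * pool, j * pool:(j + 1) * pool]
                cnt = win.shape[2] * win.shape[3]
                win += g[:, :, i:i + 1, j:j + 1] / cnt
        return (dx,)

    return Node(y, (x,), grad_fn)


def _interp_matrix(n_out, n_in):
    """Row-stochastic linear-interpolation matrix (align_corners=False)."""
    a = np.zeros((n_out, n_in), dtype=F32)
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    t = (src - i0).astype(F32)
    a[np.arange(n_out), i0] += 1 - t
    a[np.arange(n_out), i1] += t
    return a


def bilinear_resize(x: Node, out_hw) -> Node:
    x = as_node(x)
    n, c, h, w = x.data.shape
    ho, wo = out_hw
    if (ho, wo) == (h, w):
        return Node(x.data.copy(), (x,), lambda g: (g,))
    ah = _interp_matrix(ho, h)
    aw = _interp_matrix(wo, w)
    y = np.einsum("oh,nchw,pw->ncop", ah, x.data, aw, optimize=True)

    def grad_fn(g):
        dx = np.einsum("oh,ncop,pw->nchw", ah, g, aw, optimize=True)
        return (dx,)

    return Node(y.astype(F32), (x,), grad_fn)


def batchnorm2d(x: Node, gamma: Node, beta: Node, running_mean, running_var,
                training: bool, momentum: float = 0.9, eps: float = 1e-5) -> Node:
    """Per-channel batch normalization over (N, H, W).

    ``running_mean``/``running_var`` are plain arrays updated in place in
    training mode (they are statistics, not trainable parameters).
    """
    x, gamma, beta = as_node(x), as_node(gamma), as_node(beta)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= momentum
        running_mean += (1 - momentum) * mu
        running_var *= momentum
        running_var += (1 - momentum) * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def grad_fn(g):
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        dbeta = g.sum(axis=(0, 2, 3))
        gx = g * gamma.data[None, :, None, None]
        if training:
            mean_gx = gx.mean(axis=(0, 2, 3))
            mean_gxxh = (gx * xhat).mean(axis=(0, 2, 3))
            dx = (gx - mean_gx[None, :, None, None]
                  - xhat * mean_gxxh[None, :, None, None]) * inv[None, :, None, None]
        else:
            dx = gx * inv[None, :, None, None]
        return dx.astype(F32), dgamma, dbeta

    return Node(y.astype(F32), (x, gamma, beta), grad_fn)


def bce_with_logits(z: Node, targets: np.ndarray) -> Node:
    """Mean binary cross-entropy from logits (numerically stable)."""
    z = as_node(z)
    t = np.asarray(targets, dtype=F32)
    zd = z.data
    # softplus(z) - t*z, stable form
    loss = np.maximum(zd, 0) - zd * t + np.log1p(np.exp(-np.abs(zd)))
    m = loss.size
    p = np.empty_like(zd)
    pos = zd >= 0
    p[pos] = 1.0 / (1.0 + np.exp(-zd[pos]))
    ez = np.exp(zd[~pos])
    p[~pos] = ez / (1.0 + ez)

    def grad_fn(g):
        return (g * (p - t) / m,)

    return Node(loss.mean(), (z,), grad_fn)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Parameter(Node):
    """A leaf tape node holding trainable weights."""

    def __init__(self, data):
        super().__init__(data)


class Module:
    """Tiny module base: tracks parameters and submodules by attribute."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, ModuleList):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def parameters(self):
        for m in self.modules():
            yield from m._params.values()

    def named_parameters(self, prefix=""):
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for mname, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{mname}.")

    def set_training(self, flag: bool):
        for m in self.modules():
            object.__setattr__(m, "training", flag)
        return self

    def buffers(self):
        """Non-trainable state arrays (batch-norm running statistics)."""
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                yield m.running_mean
                yield m.running_var

    # state snapshot helpers (for best-val restore / fine-tuning);
    # includes BN running statistics so a restored model predicts
    # exactly as it did at snapshot time
    def get_weights(self):
        return ([p.data.copy() for p in self.parameters()]
                + [b.copy() for b in self.buffers()])

    def set_weights(self, weights):
        params = list(self.parameters())
        buffers = list(self.buffers())
        if len(params) + len(buffers) != len(weights):
            raise ValueError("weight list does not match parameter count")
        for p, w in zip(params, weights):
            if p.data.shape != w.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {w.shape}")
            p.data = np.asarray(w, dtype=F32).copy()
        for b, w in zip(buffers, weights[len(params):]):
            b[...] = np.asarray(w, dtype=F32)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m):
        self._modules[str(len(self._list))] = m
        self._list.append(m)
        return self

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def __len__(self):
        return len(self._list)


class Conv2d(Module):
    def __init__(self, cin, cout, k, rng):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        std = np.sqrt(2.0 / (cin * k * k))  # He init
        self.weight = Parameter(rng.normal(0, std, (cout, cin, k, k)))
        self.bias = Parameter(np.zeros(cout))

    def __call__(self, x):
        return conv2d(x, self.weight, self.bias)


class ConvTranspose2d(Module):
    def __init__(self, cin, cout, k, rng, stride=2):
        super().__init__()
        self.stride = stride
        std = np.sqrt(2.0 / (cin * k * k))
        self.weight = Parameter(rng.normal(0, std, (cin, cout, k, k)))
        self.bias = Parameter(np.zeros(cout))

    def __call__(self, x):
        return conv_transpose2d(x, self.weight, self.bias, stride=self.stride)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.9, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def __call__(self, x):
        return batchnorm2d(x, self.gamma, self.beta,
                           self.running_mean, self.running_var,
                           self.training, self.momentum, self.eps)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the framework-era defaults beta=(0.9, 0.999), eps=1e-7."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
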