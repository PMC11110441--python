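"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Only the operations required by a small encoder-decoder transformer are
implemented: broadcast add, elementwise multiply, (batched) matmul,
transpose/reshape, ReLU, softmax, layer normalisation, embedding lookup,
dropout, row stacking and a fused softmax cross-entropy.  Gradients are
accumulated by a topological backward sweep over the recorded tape.

The engine is deliberately eager and single-threaded: given fixed inputs
and seeds, forward and backward passes are bitwise reproducible, which the
training contracts rely on.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Adam", "gradcheck", "set_default_dtype", "get_default_dtype"]

_DEFAULT_DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    """Set the dtype newly created tensors use (float64 default; float32 for
    speed-critical desk-scale training where 1e-6-level gradient accuracy
    suffices)."""
    global _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype).type


def get_default_dtype():
    return _DEFAULT_DTYPE


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an attached gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _result(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = np.asarray(data)
        out.grad = None
        out.requires_grad = False
        out._backward = None
        out._parents = ()
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=self.data.dtype), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = Tensor._wrap(other)

        def backward(g):
            self._accum(g)
            other._accum(g)

        return Tensor._result(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            self._accum(-g)

        return Tensor._result(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._wrap(other))

    def __mul__(self, other) -> "Tensor":
        other = Tensor._wrap(other)

        def backward(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._result(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._wrap(other)

        def backward(g):
            self._accum(g @ np.swapaxes(other.data, -1, -2))
            other._accum(np.swapaxes(self.data, -1, -2) @ g)

        return Tensor._result(self.data @ other.data, (self, other), backward)

    def transpose(self, *axes: int) -> "Tensor":
        inv = np.argsort(axes)

        def backward(g):
            self._accum(np.transpose(g, inv))

        return Tensor._result(np.transpose(self.data, axes), (self,), backward)

    def reshape(self, *shape: int) -> "Tensor":
        orig = self.data.shape

        def backward(g):
            self._accum(g.reshape(orig))

        return Tensor._result(self.data.reshape(shape), (self,), backward)

    # -- nonlinearities and normalisation -------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._result(self.data * mask, (self,), backward)

    def softmax(self) -> "Tensor":
        """Softmax over the last axis."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            self._accum(s * (g - (g * s).sum(axis=-1, keepdims=True)))

        return Tensor._result(s, (self,), backward)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5) -> "Tensor":
        """Normalise over the last axis, then scale and shift."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        n = self.data.shape[-1]

        def backward(g):
            gamma._accum((g * xhat).sum(axis=tuple(range(g.ndim - 1))))
            beta._accum(g.sum(axis=tuple(range(g.ndim - 1))))
            gx = g * gamma.data
            # d/dx of (x - mu) * inv
            dx = inv * (gx - gx.mean(axis=-1, keepdims=True)
                        - xhat * (gx * xhat).mean(axis=-1, keepdims=True))
            self._accum(dx)

        return Tensor._result(xhat * gamma.data + beta.data, (self, gamma, beta), backward)

    # -- indexing / shaping ----------------------------------------------------
    def rows(self, idx) -> "Tensor":
        """Row gather (embedding lookup): self[idx] for an int array `idx`."""
        idx = np.asarray(idx, dtype=np.intp)

        def backward(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            self._accum(acc)

        return Tensor._result(self.data[idx], (self,), backward)

    @staticmethod
    def concat(parts: Iterable["Tensor"], axis: int = 0) -> "Tensor":
        """Concatenate tensors along an arbitrary axis."""
        parts = [Tensor._wrap(p) for p in parts]
        sizes = [p.data.shape[axis] for p in parts]

        def backward(g):
            off = 0
            for p, n in zip(parts, sizes):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(off, off + n)
                p._accum(g[tuple(sl)])
                off += n

        return Tensor._result(
            np.concatenate([p.data for p in parts], axis=axis), parts, backward)

    @staticmethod
    def concat_rows(parts: Iterable["Tensor"]) -> "Tensor":
        """Concatenate 2-D tensors along axis 0."""
        parts = [Tensor._wrap(p) for p in parts]
        sizes = [p.data.shape[0] for p in parts]

        def backward(g):
            off = 0
            for p, n in zip(parts, sizes):
                p._accum(g[off:off + n])
                off += n

        return Tensor._result(np.concatenate([p.data for p in parts], axis=0), parts, backward)

    def dropout(self, p: float, rng: np.random.Generator | None) -> "Tensor":
        """Inverted dropout; identity when `rng` is None or p == 0."""
        if rng is None or p <= 0.0:
            return self
        keep = (rng.random(self.data.shape) >= p) / (1.0 - p)

        def backward(g):
            self._accum(g * keep)

        return Tensor._result(self.data * keep, (self,), backward)

    # -- reductions and losses --------------------------------------------------
    def mean(self) -> "Tensor":
        n = self.data.size

        def backward(g):
            self._accum(np.full(self.data.shape, float(g) / n))

        return Tensor._result(self.data.mean(), (self,), backward)

    def cross_entropy(self, targets) -> "Tensor":
        """Mean token-level cross-entropy of logits (T, V) against int targets (T,)."""
        targets = np.asarray(targets, dtype=np.intp)
        z = self.data - self.data.max(axis=-1, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
        logp = z - lse
        n = targets.shape[0]
        loss = -logp[np.arange(n), targets].mean()

        def backward(g):
            grad = np.exp(logp)
            grad[np.arange(n), targets] -= 1.0
            self._accum(grad * (float(g) / n))

        return Tensor._result(loss, (self,), backward)

    def cross_entropy_weighted(self, targets, weights) -> "Tensor":
        """Weighted cross-entropy of logits (..., V) against int targets.

        `weights` has the targets' shape; the result is sum(w_i * CE_i).
        Padding positions get weight zero; per-sequence mean then batch mean
        corresponds to w = 1 / (sequence_length * batch_size).
        """
        targets = np.asarray(targets, dtype=np.intp)
        weights = np.asarray(weights, dtype=self.data.dtype)
        z = self.data - self.data.max(axis=-1, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
        logp = z - lse
        picked = np.take_along_axis(logp, targets[..., None], axis=-1)[..., 0]
        loss = -(picked * weights).sum()

        def backward(g):
            grad = np.exp(logp)
            np.put_along_axis(
                grad, targets[..., None],
                np.take_along_axis(grad, targets[..., None], axis=-1) - 1.0,
                axis=-1)
            self._accum(grad * (weights * float(g))[..., None])

        return Tensor._result(loss, (self,), backward)

    # -- autodiff driver ---------------------------------------------------------
    def backward(self) -> None:
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(1.0)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Fused affine map x @ w + b for 2-D (or stacked) x."""

    def backward(g):
        x._accum(g @ np.swapaxes(w.data, -1, -2))
        w._accum(np.swapaxes(x.data, -1, -2) @ g if g.ndim == 2
                 else np.tensordot(x.data, g, axes=(tuple(range(g.ndim - 1)),) * 2))
        b._accum(g.sum(axis=tuple(range(g.ndim - 1))))

    return Tensor._result(x.data @ w.data + b.data, (x, w, b), backward)


def attention(xq: Tensor, xkv: Tensor, wq: Tensor, bq: Tensor, wk: Tensor,
              bk: Tensor, wv: Tensor, bv: Tensor, wo: Tensor, bo: Tensor,
              n_heads: int, mask: np.ndarray | None = None) -> Tensor:
    """Fused multi-head attention with a hand-derived backward pass.

    `xq` provides queries, `xkv` keys and values; both may be (T, d) or
    batched (B, T, d).  `mask` is an additive (Tq, Tk) array (e.g. the causal
    mask) or None.  Equivalent to composing the primitive ops but records a
    single tape node, which keeps training fast.
    """
    batched = xq.data.ndim == 3
    tq, d = xq.data.shape[-2], xq.data.shape[-1]
    tk = xkv.data.shape[-2]
    dh = d // n_heads
    red = tuple(range(xq.data.ndim - 1))  # axes to contract for weight grads

    def heads(m, t):
        if batched:
            return m.reshape(m.shape[0], t, n_heads, dh).transpose(0, 2, 1, 3)
        return m.reshape(t, n_heads, dh).transpose(1, 0, 2)

    def unheads(m, t):
        if batched:
            return m.transpose(0, 2, 1, 3).reshape(m.shape[0], t, d)
        return m.transpose(1, 0, 2).reshape(t, d)

    qm = xq.data @ wq.data + bq.data
    km = xkv.data @ wk.data + bk.data
    vm = xkv.data @ wv.data + bv.data
    q, k, v = heads(qm, tq), heads(km, tk), heads(vm, tk)
    scale = 1.0 / np.sqrt(dh)
    s = q @ np.swapaxes(k, -1, -2) * scale
    if mask is not None:
        s = s + mask.astype(s.dtype, copy=False)
    s -= s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    p = e / e.sum(axis=-1, keepdims=True)
    o = p @ v
    om = unheads(o, tq)
    out = om @ wo.data + bo.data

    def backward(g):
        bo._accum(g.sum(axis=red))
        wo._accum(np.tensordot(om, g, axes=(red, red)))
        do = heads(g @ wo.data.T, tq)
        dp = do @ np.swapaxes(v, -1, -2)
        dv = np.swapaxes(p, -1, -2) @ do
        ds = p * (dp - (dp * p).sum(axis=-1, keepdims=True))
        ds *= scale
        dq = ds @ k
        dk = np.swapaxes(ds, -1, -2) @ q
        dqm = unheads(dq, tq)
        dkm = unheads(dk, tk)
        dvm = unheads(dv, tk)
        wq._accum(np.tensordot(xq.data, dqm, axes=(red, red)))
        bq._accum(dqm.sum(axis=red))
        wk._accum(np.tensordot(xkv.data, dkm, axes=(red, red)))
        bk._accum(dkm.sum(axis=red))
        wv._accum(np.tensordot(xkv.data, dvm, axes=(red, red)))
        bv._accum(dvm.sum(axis=red))
        xq._accum(dqm @ wq.data.T)
        xkv._accum(dkm @ wk.data.T + dvm @ wv.data.T)

    return Tensor._result(out, (xq, xkv, wq, bq, wk, bk, wv, bv, wo, bo), backward)


class Adam:
    """Adam optimiser over a dict of named parameter tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        step = self.lr / b1t
        eps = self.eps * math.sqrt(b2t)
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            m, v = self.m[k], self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * np.square(g)
            # in-place: p -= step * m / (sqrt(v/b2t) + eps_hat), rescaled by sqrt(b2t)
            denom = np.sqrt(v)
            denom += eps
            p.data -= (step * math.sqrt(b2t)) * m / denom


def gradcheck(fn: Callable[[list[Tensor]], Tensor], tensors: list[Tensor],
              eps: float = 1e-6, rtol: float = 1e-4, atol: float = 1e-6) -> bool:
    """Compare analytic gradients of scalar `fn` with central differences."""
    for t in tensors:
        t.grad = None
    out = fn(tensors)
    out.backward()
    for t in tensors:
        if not t.requires_grad:
            continue
        num = np.zeros_like(t.data)
        flat = t.data.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = float(fn(tensors).data)
            flat[i] = orig - eps
            lo = float(fn(tensors).data)
            flat[i] = orig
            num.ravel()[i] = (hi - lo) / (2 * eps)
        if not np.allclose(t.grad, num, rtol=rtol, atol=atol):
            return False
    return True
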