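"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the graph network and consensus network
need: affine maps, leaky-ReLU, sigmoid, concatenation, row gather,
segment-sum/mean (for message aggregation) and a numerically stable binary
cross-entropy on logits. float32 throughout.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

DTYPE = np.float32


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data: np.ndarray, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: np.ndarray, own: bool = False) -> None:
        # `own=True` promises g is a freshly allocated DTYPE array that the
        # caller will not reuse, so it can be adopted without copying
        if self.grad is None:
            if own and g.dtype == DTYPE and g.flags["OWNDATA"]:
                self.grad = g
            else:
                self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from a scalar tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                if node is not self:
                    node.grad = None  # free intermediate grads promptly


def _make(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
    out._parents = tuple(p for p in parents if p.requires_grad)
    return out


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x @ w + b (row-broadcast bias)."""
    out = _make(x.data @ w.data + b.data, (x, w, b))

    def _backward(grad: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(grad @ w.data.T, own=True)
        if w.requires_grad:
            w._accumulate(x.data.T @ grad, own=True)
        if b.requires_grad:
            b._accumulate(grad.sum(axis=0), own=True)

    out._backward = _backward
    return out


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    factor = np.where(x.data > 0, DTYPE(1.0), DTYPE(slope))
    out = _make(x.data * factor, (x,))

    def _backward(grad: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(grad * factor, own=True)

    out._backward = _backward
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data.astype(np.float64)))
    s = s.astype(DTYPE)
    out = _make(s, (x,))

    def _backward(grad: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(grad * s * (1.0 - s), own=True)

    out._backward = _backward
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _backward(grad: np.ndarray) -> None:
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * grad.ndim
                sl[axis] = slice(start, stop)
                t._accumulate(grad[tuple(sl)])

    out._backward = _backward
    return out


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    out = _make(x.data[idx], (x,))

    def _backward(grad: np.ndarray) -> None:
        if x.requires_grad:
            g = np.zeros_like(x.data)
            np.add.at(g, idx, grad)
            x._accumulate(g, own=True)

    out._backward = _backward
    return out


def segment_mean(x: Tensor, seg_ids: np.ndarray, num_segments: int) -> Tensor:
    """Mean of rows of ``x`` grouped by ``seg_ids``; empty segments get 0."""
    counts = np.bincount(seg_ids, minlength=num_segments).astype(DTYPE)
    safe = np.maximum(counts, 1.0)[:, None]
    summed = np.zeros((num_segments, x.data.shape[1]), dtype=DTYPE)
    np.add.at(summed, seg_ids, x.data)
    out = _make(summed / safe, (x,))

    def _backward(grad: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate((grad / safe)[seg_ids], own=True)

    out._backward = _backward
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise sum of two same-shape tensors."""
    if a.data.shape != b.data.shape:
        raise ValueError("add requires matching shapes")
    out = _make(a.data + b.data, (a, b))

    def _backward(grad: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(grad)
        if b.requires_grad:
            b._accumulate(grad)

    out._backward = _backward
    return out


def mul_const(x: Tensor, c: np.ndarray | float) -> Tensor:
    """Multiply by a constant (broadcastable) array; no grad flows into c."""
    c_arr = np.asarray(c, dtype=DTYPE)
    out = _make(x.data * c_arr, (x,))

    def _backward(grad: np.ndarray) -> None:
        if x.requires_grad:
            g = grad * c_arr
            if g.shape != x.data.shape:
                # undo broadcasting
                extra = g.ndim - x.data.ndim
                if extra:
                    g = g.sum(axis=tuple(range(extra)))
                axes = tuple(
                    i for i, (gs, xs) in enumerate(zip(g.shape, x.data.shape)) if xs == 1 and gs != 1
                )
                if axes:
                    g = g.sum(axis=axes, keepdims=True)
            x._accumulate(g)

    out._backward = _backward
    return out


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    out = _make(x.data.reshape(shape), (x,))

    def _backward(grad: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(grad.reshape(x.data.shape))

    out._backward = _backward
    return out


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice [start, start+length) along one axis."""
    sl = [slice(None)] * x.data.ndim
    sl[axis] = slice(start, start + length)
    out = _make(x.data[tuple(sl)], (x,))

    def _backward(grad: np.ndarray) -> None:
        if x.requires_grad:
            g = np.zeros_like(x.data)
            g[tuple(sl)] = grad
            x._accumulate(g, own=True)

    out._backward = _backward
    return out


def pad_axis(x: Tensor, axis: int, before: int, after: int) -> Tensor:
    """Zero-pad along one axis."""
    widths = [(0, 0)] * x.data.ndim
    widths[axis] = (before, after)
    out = _make(np.pad(x.data, widths), (x,))
    sl = [slice(None)] * x.data.ndim
    sl[axis] = slice(before, before + x.data.shape[axis])

    def _backward(grad: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(grad[tuple(sl)])

    out._backward = _backward
    return out


def sum_axis(x: Tensor, axis: int) -> Tensor:
    out = _make(x.data.sum(axis=axis), (x,))

    def _backward(grad: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(np.broadcast_to(np.expand_dims(grad, axis), x.data.shape))

    out._backward = _backward
    return out


def chain_incoming_mean(
    e_f: Tensor, e_b: Tensor, edge_mask: np.ndarray, inv_deg: np.ndarray
) -> Tensor:
    """Per-node mean of incoming directed-edge features on batched chain
    graphs. ``e_f``/``e_b`` are (B, L-1, d) forward/backward edge features,
    ``edge_mask`` (B, L-1, 1) zeroes padded adjacencies, ``inv_deg``
    (B, L, 1) is 1/in-degree (0 on padded nodes). Node v receives forward
    edge v-1 and backward edge v."""
    ef = e_f.data * edge_mask
    eb = e_b.data * edge_mask
    b, lm1, d = ef.shape
    out_arr = np.zeros((b, lm1 + 1, d), dtype=DTYPE)
    out_arr[:, 1:] += ef
    out_arr[:, :-1] += eb
    out_arr *= inv_deg
    out = _make(out_arr, (e_f, e_b))

    def _backward(grad: np.ndarray) -> None:
        g = grad * inv_deg
        if e_f.requires_grad:
            e_f._accumulate(g[:, 1:] * edge_mask, own=True)
        if e_b.requires_grad:
            e_b._accumulate(g[:, :-1] * edge_mask, own=True)

    out._backward = _backward
    return out


def masked_mean_axis1(x: Tensor, mask: np.ndarray, inv_count: np.ndarray) -> Tensor:
    """Masked mean over axis 1: ``(x * mask).sum(1) * inv_count`` with
    mask (B, L, 1) and inv_count (B, 1)."""
    out = _make((x.data * mask).sum(axis=1) * inv_count, (x,))

    def _backward(grad: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate((grad * inv_count)[:, None, :] * mask, own=True)

    out._backward = _backward
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (stable log-sum-exp form)."""
    z = logits.data.astype(np.float64).ravel()
    t = np.asarray(targets, dtype=np.float64).ravel()
    if z.shape != t.shape:
        raise ValueError("logits and targets must have matching size")
    # loss_i = max(z,0) - z*t + log(1 + exp(-|z|))
    loss = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out = _make(np.array(loss.mean(), dtype=DTYPE), (logits,))
    p = 1.0 / (1.0 + np.exp(-z))

    def _backward(grad: np.ndarray) -> None:
        if logits.requires_grad:
            g = ((p - t) / z.size).astype(DTYPE).reshape(logits.data.shape)
            logits._accumulate(grad * g)

    out._backward = _backward
    return out


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            m_hat = m / (1 - b1**self._t)
            v_hat = v / (1 - b2**self._t)
            p.data -= self.lr * (
                m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data
            )


def kaiming_uniform(
    rng: np.random.Generator, fan_in: int, fan_out: int, slope: float = 0.01
) -> np.ndarray:
    """Fan-based uniform initialization for leaky-ReLU layers."""
    gain = np.sqrt(2.0 / (1.0 + slope**2))
    bound = gain * np.sqrt(3.0 / fan_in)
    return rng.uniform(-bound, bound, size=(fan_in, fan_out)).astype(DTYPE)


class MLP:
    """Fully connected stack with leaky-ReLU between layers.

    ``activate_final=False`` leaves the last layer linear (logits).
    """

    def __init__(
        self,
        sizes: list[int],
        rng: np.random.Generator,
        slope: float = 0.01,
        activate_final: bool = False,
    ):
        if len(sizes) < 2:
            raise ValueError("MLP needs at least input and output sizes")
        self.sizes = list(sizes)
        self.slope = slope
        self.activate_final = activate_final
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            self.weights.append(
                Tensor(kaiming_uniform(rng, fan_in, fan_out, slope), requires_grad=True)
            )
            bound = 1.0 / np.sqrt(fan_in)
            self.biases.append(
                Tensor(
                    rng.uniform(-bound, bound, size=(fan_out,)).astype(DTYPE),
                    requires_grad=True,
                )
            )

    @property
    def params(self) -> list[Tensor]:
        out: list[Tensor] = []
        for w, b in zip(self.weights, self.biases):
            out.extend([w, b])
        return out

    @property
    def n_params(self) -> int:
        return sum(p.data.size for p in self.params)

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = linear(h, w, b)
            if i < last or self.activate_final:
                h = leaky_relu(h, self.slope)
        return h

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        params = self.params
        if len(arrays) != len(params):
            raise ValueError("state length mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state shape mismatch")
            p.data = np.asarray(a, dtype=DTYPE).copy()
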