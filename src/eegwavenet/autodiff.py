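"""A small reverse-mode automatic-differentiation engine over numpy arrays.

Only the operations the dual-path network needs are provided: broadcasting
arithmetic, matmul, the activations, causal dilated 1-D convolution (im2col
forward, col2im backward), temporal average pooling, an LSTM returning its
final hidden state (hand-written truncated-free BPTT), softmax
cross-entropy, dropout, and shape ops.  Gradients of every op are checked
against central finite differences in the test suite.

Tensors hold float32 by default; float64 works too (the gradient-check
tests use it).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "concat", "softmax_cross_entropy"]


class Tensor:
    """A numpy array plus gradient bookkeeping for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        """Accumulate gradients of this (scalar unless grad given) node."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad):
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _unbroadcast(grad, shape):
        """Sum a gradient over axes that were broadcast in the forward op."""
        extra = grad.ndim - len(shape)
        if extra:
            grad = grad.sum(axis=tuple(range(extra)))
        axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
        if axes:
            grad = grad.sum(axis=axes, keepdims=True)
        return grad

    @staticmethod
    def _wrap(x):
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(self._unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(self._unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(self._unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(self._unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(self._unbroadcast(gb, other.shape))

        out._backward = backward
        return out

    # -- activations -------------------------------------------------------

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - y * y))

        out._backward = backward
        return out

    def sigmoid(self):
        y = expit(self.data)
        out = Tensor(y, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * y * (1.0 - y))

        out._backward = backward
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = backward
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, parents=(self,))

        def backward(g):
            if self.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accum(y * (g - dot))

        out._backward = backward
        return out

    # -- reductions and shape ----------------------------------------------

    def mean(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.mean(axis=axis, keepdims=keepdims), parents=(self,))
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])

        def backward(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if not keepdims and axis is not None:
                gg = np.expand_dims(gg, axis=axis)
            self._accum(np.broadcast_to(gg, self.shape) / n)

        out._backward = backward
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if not keepdims and axis is not None:
                gg = np.expand_dims(gg, axis=axis)
            self._accum(np.broadcast_to(gg, self.shape).astype(self.dtype))

        out._backward = backward
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))

        out._backward = backward
        return out

    def flip_time(self, axis: int = 1):
        """Reverse along a time axis (used for input 'flipping')."""
        out = Tensor(np.flip(self.data, axis=axis).copy(), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(np.flip(g, axis=axis))

        out._backward = backward
        return out

    # -- network-specific ops ----------------------------------------------

    def causal_conv1d(self, w: "Tensor", b: "Tensor", dilation: int = 1):
        """Causal dilated 1-D convolution.

        ``self`` is ``(N, L, Cin)``; ``w`` is ``(k, Cin, F)``; ``b`` is
        ``(F,)``.  The sequence is left-padded with ``(k-1)*dilation`` zeros
        so output length equals input length and position ``t`` depends only
        on inputs at times ``<= t``.
        """
        x = self.data
        n, length, cin = x.shape
        k, cin_w, f = w.data.shape
        assert cin == cin_w, (cin, cin_w)
        pad = (k - 1) * dilation
        xp = np.pad(x, ((0, 0), (pad, 0), (0, 0)))
        y = np.broadcast_to(b.data, (n, length, f)).copy()
        for j in range(k):
            y += xp[:, j * dilation: j * dilation + length, :] @ w.data[j]
        out = Tensor(y, parents=(self, w, b))

        def backward(g):
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 1)))
            if w.requires_grad:
                dw = np.empty_like(w.data)
                for j in range(k):
                    xs = xp[:, j * dilation: j * dilation + length, :]
                    dw[j] = np.tensordot(xs, g, axes=([0, 1], [0, 1]))
                w._accum(dw)
            if self.requires_grad:
                dxp = np.zeros_like(xp)
                for j in range(k):
                    dxp[:, j * dilation: j * dilation + length, :] += g @ w.data[j].T
                self._accum(dxp[:, pad:, :])

        out._backward = backward
        return out

    def avg_pool1d(self, factor: int):
        """Non-overlapping temporal average pooling on ``(N, L, C)``.

        A trailing remainder of fewer than ``factor`` steps is dropped.
        """
        n, length, c = self.shape
        lp = length // factor
        x = self.data[:, : lp * factor, :].reshape(n, lp, factor, c)
        out = Tensor(x.mean(axis=2), parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            dx = np.zeros(self.shape, dtype=self.dtype)
            dx[:, : lp * factor, :] = np.repeat(g / factor, factor, axis=1)
            self._accum(dx)

        out._backward = backward
        return out

    def lstm_last(self, wx: "Tensor", wh: "Tensor", b: "Tensor"):
        """LSTM over ``(N, T, Cin)`` returning the final hidden state ``(N, U)``.

        Single-bias convention; gate order [input, forget, cell, output];
        zero initial state.  Backward is a hand-written BPTT that only needs
        the gradient of the last hidden state, which is all the architecture
        uses.
        """
        x = self.data
        n, t_steps, cin = x.shape
        units = wh.data.shape[0]
        i_s = np.empty((t_steps, n, units), dtype=x.dtype)
        f_s = np.empty_like(i_s)
        g_s = np.empty_like(i_s)
        o_s = np.empty_like(i_s)
        tc_s = np.empty_like(i_s)  # tanh(c_t)
        c_prev_s = np.empty_like(i_s)
        h = np.zeros((n, units), dtype=x.dtype)
        c = np.zeros((n, units), dtype=x.dtype)
        xw = x.reshape(n * t_steps, cin) @ wx.data  # precompute input paths
        xw = xw.reshape(n, t_steps, 4 * units)
        for t in range(t_steps):
            pre = xw[:, t, :] + h @ wh.data + b.data
            i_g = expit(pre[:, :units])
            f_g = expit(pre[:, units:2 * units])
            g_g = np.tanh(pre[:, 2 * units:3 * units])
            o_g = expit(pre[:, 3 * units:])
            c_prev_s[t] = c
            c = f_g * c + i_g * g_g
            tc = np.tanh(c)
            h = o_g * tc
            i_s[t], f_s[t], g_s[t], o_s[t], tc_s[t] = i_g, f_g, g_g, o_g, tc
        out = Tensor(h, parents=(self, wx, wh, b))

        def backward(grad_h):
            dwx = np.zeros_like(wx.data)
            dwh = np.zeros_like(wh.data)
            db = np.zeros_like(b.data)
            dx = np.zeros_like(x) if self.requires_grad else None
            dh = np.asarray(grad_h).copy()
            dc = np.zeros_like(dh)
            dpre = np.empty((n, 4 * units), dtype=x.dtype)
            for t in range(t_steps - 1, -1, -1):
                i_g, f_g, g_g, o_g, tc = i_s[t], f_s[t], g_s[t], o_s[t], tc_s[t]
                do = dh * tc
                dct = dc + dh * o_g * (1.0 - tc * tc)
                di = dct * g_g
                dg = dct * i_g
                df = dct * c_prev_s[t]
                dc = dct * f_g
                dpre[:, :units] = di * i_g * (1.0 - i_g)
                dpre[:, units:2 * units] = df * f_g * (1.0 - f_g)
                dpre[:, 2 * units:3 * units] = dg * (1.0 - g_g * g_g)
                dpre[:, 3 * units:] = do * o_g * (1.0 - o_g)
                h_prev = o_s[t - 1] * tc_s[t - 1] if t > 0 else np.zeros_like(dh)
                dwx += x[:, t, :].T @ dpre
                dwh += h_prev.T @ dpre
                db += dpre.sum(axis=0)
                if dx is not None:
                    dx[:, t, :] = dpre @ wx.data.T
                dh = dpre @ wh.data.T
            if wx.requires_grad:
                wx._accum(dwx)
            if wh.requires_grad:
                wh._accum(dwh)
            if b.requires_grad:
                b._accum(db)
            if dx is not None:
                self._accum(dx)

        out._backward = backward
        return out

    def dropout(self, p: float, rng: np.random.Generator, train: bool):
        """Inverted dropout: active only when ``train`` and ``p > 0``."""
        if not train or p <= 0.0:
            return self
        mask = (rng.random(self.shape) >= p).astype(self.dtype) / (1.0 - p)
        out = Tensor(self.data * mask, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = backward
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along an axis."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)

    out._backward = backward
    return out


def softmax_cross_entropy(logits: Tensor, y: np.ndarray
                          ) -> tuple[Tensor, np.ndarray]:
    """Mean cross-entropy of integer targets; also returns the probabilities."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    nll = -np.log(np.maximum(probs[np.arange(n), y], 1e-12))
    out = Tensor(np.array(nll.mean(), dtype=logits.dtype), parents=(logits,))

    def backward(g):
        if logits.requires_grad:
            d = probs.copy()
            d[np.arange(n), y] -= 1.0
            logits._accum((g / n) * d.astype(logits.dtype))

    out._backward = backward
    return out, probs
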