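"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough tape machinery to train the cross-modal attention network:
broadcast-aware elementwise arithmetic, (batched) matmul, ReLU, sigmoid,
softmax, a fused layer norm, dropout and a fused weighted binary
cross-entropy on logits.  Gradients are checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "matmul", "relu", "sigmoid", "softmax", "layer_norm",
    "dropout", "concat_last", "transpose_last2", "bce_with_logits", "Adam",
    "set_default_dtype", "get_default_dtype",
]

#: float32 keeps training memory-bandwidth-bound steps fast; tests that
#: finite-difference-check gradients switch to float64 for headroom.
_DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global _DTYPE
    if np.dtype(dtype) not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("dtype must be float32 or float64")
    _DTYPE = np.dtype(dtype).type


def get_default_dtype():
    return _DTYPE


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "parents", "_bwd", "requires_grad")

    def __init__(self, data, parents=(), bwd=None, requires_grad=False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.parents = parents
        self._bwd = bwd
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self.grad = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction -------------------------------------------------

    def _make(self, data, parents, bwd):
        return Tensor(data, parents=parents, bwd=bwd)

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))
        return self._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data
        a, b = self, other

        def bwd(g):
            return (_unbroadcast(g * b.data, a.shape),
                    _unbroadcast(g * a.data, b.shape))
        return self._make(out_data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        out_data = a.data / b.data

        def bwd(g):
            return (_unbroadcast(g / b.data, a.shape),
                    _unbroadcast(-g * a.data / b.data ** 2, b.shape))
        return self._make(out_data, (a, b), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g, out_data=out_data):
            return (g * 0.5 / np.maximum(out_data, 1e-300),)
        return self._make(out_data, (self,), bwd)

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, shape).copy(),)
        return self._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.shape
        return self._make(self.data.reshape(*shape), (self,),
                          lambda g: (g.reshape(old),))

    # -- autodiff -----------------------------------------------------------

    def backward(self, grad=None):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)
        visit(self)
        self.grad = np.ones_like(self.data) if grad is None \
            else np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._bwd is None or t.grad is None:
                continue
            for p, g in zip(t.parents, t._bwd(t.grad)):
                if not p.requires_grad or g is None:
                    continue
                p.grad = g if p.grad is None else p.grad + g

    def zero_grad(self):
        self.grad = None


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with numpy broadcasting of leading axes.
    Gradients are only formed for operands that require them."""
    out_data = np.matmul(a.data, b.data)
    need_a, need_b = a.requires_grad, b.requires_grad

    def bwd(g):
        ga = _unbroadcast(np.matmul(g, np.swapaxes(b.data, -1, -2)),
                          a.shape) if need_a else None
        gb = _unbroadcast(np.matmul(np.swapaxes(a.data, -1, -2), g),
                          b.shape) if need_b else None
        return (ga, gb)
    return Tensor(out_data, (a, b), bwd)


def transpose_last2(a: Tensor) -> Tensor:
    return Tensor(np.swapaxes(a.data, -1, -2), (a,),
                  lambda g: (np.swapaxes(g, -1, -2),))


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    return Tensor(np.maximum(a.data, 0), (a,), lambda g: (g * mask,))


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))

    def bwd(g, out_data=out_data):
        return (g * out_data * (1.0 - out_data),)
    return Tensor(out_data, (a,), bwd)


def softmax(a: Tensor) -> Tensor:
    """Softmax over the last axis (rows sum to one)."""
    e = a.data - a.data.max(axis=-1, keepdims=True)
    np.exp(e, out=e)
    e /= e.sum(axis=-1, keepdims=True)

    def bwd(g, y=e):
        out = g - (g * y).sum(axis=-1, keepdims=True)
        out *= y
        return (out,)
    return Tensor(e, (a,), bwd)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Per-position normalization over the last (feature) axis with learned
    gain and bias."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc ** 2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gain.data + bias.data
    D = x.data.shape[-1]

    def bwd(g):
        ggain = _unbroadcast(g * xhat, gain.shape)
        gbias = _unbroadcast(g, bias.shape)
        gx_hat = g * gain.data
        gx = inv * (gx_hat
                    - gx_hat.mean(axis=-1, keepdims=True)
                    - xhat * (gx_hat * xhat).mean(axis=-1, keepdims=True))
        return (gx, ggain, gbias)
    return Tensor(out_data, (x, gain, bias), bwd)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0:
        return x
    dt = x.data.dtype
    mask = rng.random(x.shape, dtype=dt if dt == np.float32 else np.float64)
    np.greater_equal(mask, p, out=mask, casting="unsafe")
    mask *= 1.0 / (1.0 - p)
    return Tensor(x.data * mask, (x,), lambda g: (g * mask,))


def concat_last(tensors) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=-1)
    sizes = [t.data.shape[-1] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=-1))
    return Tensor(out_data, tuple(tensors), bwd)


def bce_with_logits(logits: Tensor, targets: np.ndarray,
                    sample_weight: np.ndarray | None = None) -> Tensor:
    """Mean weighted binary cross-entropy of sigmoid units, fused for
    numerical stability.

    ``logits``: [B x K]; ``targets``: one-hot [B x K]; ``sample_weight``:
    per-sample weights [B] (e.g. inverse class frequency of each sample's
    true class).
    """
    z = logits.data
    y = np.asarray(targets, dtype=np.float64)
    w = np.ones(z.shape[0]) if sample_weight is None \
        else np.asarray(sample_weight, dtype=np.float64)
    # log(1 + exp(-|z|)) + max(z, 0) - z*y  is BCE on logits
    per = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    loss = float((per.sum(axis=1) * w).mean())
    B = z.shape[0]

    def bwd(g):
        p = 1.0 / (1.0 + np.exp(-z))
        return ((p - y) * (w[:, None] * g / B),)
    return Tensor(loss, (logits,), bwd)


def _ln_fwd(x: np.ndarray, gain: np.ndarray, bias: np.ndarray,
            eps: float = 1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    inv = 1.0 / np.sqrt((xc ** 2).mean(axis=-1, keepdims=True) + eps)
    xhat = xc * inv
    return xhat * gain + bias, xhat, inv


def _ln_bwd(gy: np.ndarray, xhat: np.ndarray, inv: np.ndarray,
            gain: np.ndarray):
    gg = gy * gain
    gx = inv * (gg - gg.mean(axis=-1, keepdims=True)
                - xhat * (gg * xhat).mean(axis=-1, keepdims=True))
    axes = tuple(range(gy.ndim - 1))
    return gx, (gy * xhat).sum(axis=axes), gy.sum(axis=axes)


def _wgrad(x: np.ndarray, g: np.ndarray) -> np.ndarray:
    return x.reshape(-1, x.shape[-1]).T @ g.reshape(-1, g.shape[-1])


def _dropout_mask(shape, p, rng, dtype):
    mask = rng.random(shape, dtype=dtype if dtype == np.dtype(np.float32)
                      else np.float64)
    np.greater_equal(mask, p, out=mask, casting="unsafe")
    mask *= 1.0 / (1.0 - p)
    return mask


def attention_sublayer(prev: Tensor, src: Tensor, ln_p: tuple, ln_s: tuple,
                       Wq: Tensor, Wk: Tensor, Wv: Tensor, d_k: int,
                       dropout_p: float = 0.0, rng=None, training=False,
                       keep_weights=False):
    """Fused cross-modal attention sublayer:

    O_bar = Drop(CM(LN(prev), LN(src))) + LN(prev),
    CM(A, S) = softmax(A Wq (S Wk)^T / sqrt(d_k)) (S Wv).

    One tape node with a hand-derived backward; the T x T intermediates
    dominate the network's memory traffic, so fusing the sublayer matters.
    ``ln_p``/``ln_s`` are (gain, bias) Tensor pairs.  Returns
    ``(O_bar, attention_weights)`` with the weights as a plain array.
    """
    gp, bp = ln_p
    gs, bs = ln_s
    a_ln, a_hat, a_inv = _ln_fwd(prev.data, gp.data, bp.data)
    s_ln, s_hat, s_inv = _ln_fwd(src.data, gs.data, bs.data)
    scale = 1.0 / np.sqrt(d_k)
    Q = np.matmul(a_ln, Wq.data)
    Q *= scale
    K = np.matmul(s_ln, Wk.data)
    V = np.matmul(s_ln, Wv.data)

    def attention_weights():
        P = np.matmul(Q, np.swapaxes(K, -1, -2))
        P -= P.max(axis=-1, keepdims=True)
        np.exp(P, out=P)
        P /= P.sum(axis=-1, keepdims=True)
        return P

    # the T x T map is transient: freed after use and recomputed in the
    # backward pass, which keeps the working set cache-sized
    P = attention_weights()
    O = np.matmul(P, V)
    P_kept = P if keep_weights else None
    del P
    mask = None
    if training and dropout_p > 0:
        mask = _dropout_mask(O.shape, dropout_p, rng, O.dtype)
        O *= mask
    O += a_ln

    def bwd(g):
        P = attention_weights()
        gO = g * mask if mask is not None else g
        gP = np.matmul(gO, np.swapaxes(V, -1, -2))
        gV = np.matmul(np.swapaxes(P, -1, -2), gO)
        gP -= (gP * P).sum(axis=-1, keepdims=True)
        gP *= P                                     # score gradient
        gQ = np.matmul(gP, K)
        gK = np.matmul(np.swapaxes(gP, -1, -2), Q)
        g_a_ln = np.matmul(gQ, Wq.data.T)
        g_a_ln *= scale
        g_a_ln += g                                 # residual path
        g_s_ln = np.matmul(gK, Wk.data.T) + np.matmul(gV, Wv.data.T)
        g_prev, g_gp, g_bp = _ln_bwd(g_a_ln, a_hat, a_inv, gp.data)
        g_src, g_gs, g_bs = _ln_bwd(g_s_ln, s_hat, s_inv, gs.data)
        gWq = _wgrad(a_ln, gQ) * scale if Wq.requires_grad else None
        gWk = _wgrad(s_ln, gK) if Wk.requires_grad else None
        gWv = _wgrad(s_ln, gV) if Wv.requires_grad else None
        return (g_prev, g_src, g_gp, g_bp, g_gs, g_bs, gWq, gWk, gWv)

    out = Tensor(O, (prev, src, gp, bp, gs, bs, Wq, Wk, Wv), bwd)
    return out, P_kept


def ff_sublayer(x: Tensor, ln: tuple, W1: Tensor, b1: Tensor, W2: Tensor,
                b2: Tensor, dropout_p: float = 0.0, rng=None,
                training=False) -> Tensor:
    """Fused position-wise feed-forward sublayer:

    O = Drop(relu(LN(x) W1 + b1)) W2 + b2 + LN(x).
    """
    g_ln, b_ln = ln
    x_ln, xhat, inv = _ln_fwd(x.data, g_ln.data, b_ln.data)
    a1 = np.matmul(x_ln, W1.data)
    a1 += b1.data
    h = np.maximum(a1, 0)
    mask = None
    if training and dropout_p > 0:
        mask = _dropout_mask(h.shape, dropout_p, rng, h.dtype)
        h *= mask
    out_data = np.matmul(h, W2.data)
    out_data += b2.data
    out_data += x_ln

    def bwd(g):
        axes = tuple(range(g.ndim - 1))
        gh = np.matmul(g, W2.data.T)
        if mask is not None:
            gh *= mask
        gh *= a1 > 0
        g_x_ln = np.matmul(gh, W1.data.T)
        g_x_ln += g                                 # residual path
        gx, gg, gb = _ln_bwd(g_x_ln, xhat, inv, g_ln.data)
        return (gx, gg, gb,
                _wgrad(x_ln, gh) if W1.requires_grad else None,
                gh.sum(axis=axes) if b1.requires_grad else None,
                _wgrad(h, g) if W2.requires_grad else None,
                g.sum(axis=axes) if b2.requires_grad else None)

    return Tensor(out_data, (x, g_ln, b_ln, W1, b1, W2, b2), bwd)


def scaled_dot_attention(x_alpha: Tensor, x_beta: Tensor, Wq: Tensor,
                         Wk: Tensor, Wv: Tensor, d_k: int):
    """Fused cross-modal scaled dot-product attention.

    O = softmax(x_a Wq (x_b Wk)^T / sqrt(d_k)) (x_b Wv), computed as one
    tape node with a hand-derived backward pass (the T x T intermediates
    dominate the network's memory traffic, so fusing them matters).
    Returns ``(output, attention_weights)``; the weights are a plain array.
    """
    a, b = x_alpha.data, x_beta.data
    scale = 1.0 / np.sqrt(d_k)
    Q = np.matmul(a, Wq.data)
    Q *= scale
    K = np.matmul(b, Wk.data)
    V = np.matmul(b, Wv.data)
    P = np.matmul(Q, np.swapaxes(K, -1, -2))
    P -= P.max(axis=-1, keepdims=True)
    np.exp(P, out=P)
    P /= P.sum(axis=-1, keepdims=True)
    O = np.matmul(P, V)

    def bwd(gO):
        gP = np.matmul(gO, np.swapaxes(V, -1, -2))
        gV = np.matmul(np.swapaxes(P, -1, -2), gO)
        gP -= (gP * P).sum(axis=-1, keepdims=True)
        gP *= P                                     # now the score gradient
        gQ = np.matmul(gP, K)
        gK = np.matmul(np.swapaxes(gP, -1, -2), Q)
        ga = np.matmul(gQ, Wq.data.T)
        ga *= scale
        gb = np.matmul(gK, Wk.data.T) + np.matmul(gV, Wv.data.T)

        def wgrad(x, g):
            xf = x.reshape(-1, x.shape[-1])
            gf = g.reshape(-1, g.shape[-1])
            return xf.T @ gf
        gWq = wgrad(a, gQ) * scale if Wq.requires_grad else None
        gWk = wgrad(b, gK) if Wk.requires_grad else None
        gWv = wgrad(b, gV) if Wv.requires_grad else None
        return (_unbroadcast(ga, x_alpha.shape) if x_alpha.requires_grad
                else None,
                _unbroadcast(gb, x_beta.shape) if x_beta.requires_grad
                else None,
                gWq, gWk, gWv)

    out = Tensor(O, (x_alpha, x_beta, Wq, Wk, Wv), bwd)
    return out, P


class Adam:
    """Adaptive-moment estimation over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bias1
            vhat = self.v[i] / bias2
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
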