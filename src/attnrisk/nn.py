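"""Neural-network building blocks for the temporal EHR models.

Layers are thin compositions of :mod:`attnrisk.autodiff` operations:
linear maps, an LSTM (optionally bidirectional) with per-timestep masking,
pre-norm multi-head self-attention, layer normalization, a same-padded 1-D
convolution, and the Adam optimizer.  Parameters are ``Tensor`` objects with
``requires_grad=True``; modules expose ``parameters()`` and a numpy
``state_dict`` for checkpointing.

Everything runs on CPU in float64.  Model dimensions in this package are
deliberately small (tens, not hundreds), which keeps training on a single
core practical.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate, sigmoid, softmax, tanh

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "LSTM",
    "MultiHeadSelfAttention",
    "Conv1dSame",
    "Adam",
    "dropout",
]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Module:
    """Base class: parameter discovery, train/eval mode, state dict."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for name, p in params.items():
            p.data[...] = state[name]


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.W = Tensor(_glorot(rng, in_dim, out_dim), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class Embedding(Module):
    """Lookup table; row 0..n-1 are concept vectors.

    Lookup uses integer index arrays; gradients scatter-add into the table.
    """

    def __init__(self, n_rows: int, dim: int, rng: np.random.Generator, scale: float = 0.1):
        super().__init__()
        self.table = Tensor(rng.normal(0.0, scale, size=(n_rows, dim)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.table[idx]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc * (var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class _LSTMCellParams(Module):
    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        super().__init__()
        self.Wx = Tensor(_glorot(rng, input_dim, 4 * hidden_dim), requires_grad=True)
        self.Wh = Tensor(_glorot(rng, hidden_dim, 4 * hidden_dim), requires_grad=True)
        b = np.zeros(4 * hidden_dim)
        b[hidden_dim:2 * hidden_dim] = 1.0  # forget-gate bias, standard trick
        self.b = Tensor(b, requires_grad=True)
        self.hidden_dim = hidden_dim


def _run_lstm(params: _LSTMCellParams, x: Tensor, mask: np.ndarray) -> Tensor:
    """Unidirectional LSTM over (B, T, D); masked steps hold state.

    Returns hidden states (B, T, H).
    """
    B, T, _ = x.shape
    H = params.hidden_dim
    h = Tensor(np.zeros((B, H)))
    c = Tensor(np.zeros((B, H)))
    outs = []
    for t in range(T):
        xt = x[:, t, :]
        gates = xt @ params.Wx + h @ params.Wh + params.b
        i = sigmoid(gates[:, :H])
        f = sigmoid(gates[:, H:2 * H])
        g = tanh(gates[:, 2 * H:3 * H])
        o = sigmoid(gates[:, 3 * H:])
        c_new = f * c + i * g
        h_new = o * tanh(c_new)
        m = mask[:, t:t + 1].astype(float)
        c = c_new * m + c * (1.0 - m)
        h = h_new * m + h * (1.0 - m)
        outs.append(h)
    from .autodiff import stack as _stack

    return _stack(outs, axis=1)


class LSTM(Module):
    """(Bi)directional LSTM; concatenates directions when bidirectional."""

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator,
                 bidirectional: bool = True):
        super().__init__()
        self.fwd = _LSTMCellParams(input_dim, hidden_dim, rng)
        self.bwd = _LSTMCellParams(input_dim, hidden_dim, rng) if bidirectional else None
        self.bidirectional = bidirectional

    @property
    def out_dim(self) -> int:
        return self.fwd.hidden_dim * (2 if self.bidirectional else 1)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        h_f = _run_lstm(self.fwd, x, mask)
        if not self.bidirectional:
            return h_f
        # reverse only the valid prefix of each sequence (padding sits at the end)
        lengths = mask.sum(axis=1).astype(int)
        B, T, _ = x.shape
        rev_idx = np.tile(np.arange(T), (B, 1))
        for b in range(B):
            L = lengths[b]
            rev_idx[b, :L] = np.arange(L - 1, -1, -1)
        gather = (np.arange(B)[:, None], rev_idx)
        x_rev = x[gather]
        h_b_rev = _run_lstm(self.bwd, x_rev, mask)
        h_b = h_b_rev[gather]  # un-reverse: the same index map is its own inverse
        return concatenate([h_f, h_b], axis=-1)


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product self-attention with key masking.

    The last computed attention weights are stashed on ``last_weights``
    (numpy, shape (B, heads, T, T)) for diagnostics.
    """

    def __init__(self, dim: int, num_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % num_heads:
            raise ValueError(f"dim {dim} not divisible by num_heads {num_heads}")
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.out = Linear(dim, dim, rng)
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.last_weights: np.ndarray | None = None

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        B, T, D = x.shape
        h, dh = self.num_heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, T, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        key_mask = mask[:, None, None, :]  # (B,1,1,T)
        scores = scores + Tensor(np.where(key_mask, 0.0, -1e9))
        attn = softmax(scores, axis=-1)
        self.last_weights = attn.data.copy()
        ctx = attn @ v  # (B,h,T,dh)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.out(ctx)


class Conv1dSame(Module):
    """1-D convolution over the time axis with zero 'same' padding."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, kernel: int = 3):
        super().__init__()
        self.kernel = kernel
        self.W = Tensor(_glorot(rng, kernel * in_ch, out_ch, shape=(kernel, in_ch, out_ch)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, C = x.shape
        k = self.kernel
        pad = k // 2
        zpad = Tensor(np.zeros((B, pad, C)))
        xp = concatenate([zpad, x, zpad], axis=1)
        out = None
        for j in range(k):
            term = xp[:, j:j + T, :] @ self.W[j]
            out = term if out is None else out + term
        return out + self.b


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = rng.random(x.shape) >= p
    return x * Tensor(keep.astype(float) / (1.0 - p))


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
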