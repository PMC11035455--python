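"""Neural-network building blocks on top of the autograd engine.

Contains exactly the layers used by the QSAR regressor (embedding + stacked
LSTM + dense branches) and the causal policy (decoder-only transformer with
learned positional embeddings and a scalar value head).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, dropout, embedding, log_softmax, softmax, stack


class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialization."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def train(self, mode: bool = True):
        self.training = mode
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()

    def copy_from(self, other: "Module") -> None:
        self.load_state_arrays([a.copy() for a in other.state_arrays()])

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _uniform(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        scale = 1.0 / np.sqrt(in_features)
        self.weight = _uniform(rng, (in_features, out_features), scale)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(rng.normal(0.0, 0.02, size=(num_embeddings, dim)),
                             requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding(self.weight, ids)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class LSTM(Module):
    """Stacked LSTM; input (B, T, D) -> outputs (B, T, H) of the top layer.

    Gates are computed from a single fused projection per layer.  Inter-layer
    dropout follows the stacked-LSTM convention (applied to the inputs of
    layers > 0 during training).
    """

    def __init__(self, input_size: int, hidden_size: int, num_layers: int,
                 rng: np.random.Generator, dropout_p: float = 0.0):
        super().__init__()
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self.dropout_p = dropout_p
        self.cells = []
        for layer in range(num_layers):
            d_in = input_size if layer == 0 else hidden_size
            scale = 1.0 / np.sqrt(hidden_size)
            cell = Module()
            cell.w_ih = _uniform(rng, (d_in, 4 * hidden_size), scale)
            cell.w_hh = _uniform(rng, (hidden_size, 4 * hidden_size), scale)
            cell.bias = Tensor(np.zeros(4 * hidden_size), requires_grad=True)
            self.cells.append(cell)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        B, T, _ = x.shape
        H = self.hidden_size
        layer_input = x
        for li, cell in enumerate(self.cells):
            if li > 0 and self.dropout_p > 0 and self.training:
                layer_input = dropout(layer_input, self.dropout_p, rng, self.training)
            h = Tensor(np.zeros((B, H)))
            c = Tensor(np.zeros((B, H)))
            outs = []
            for t in range(T):
                xt = layer_input[:, t, :]
                gates = xt @ cell.w_ih + h @ cell.w_hh + cell.bias
                i = gates[:, 0:H].sigmoid()
                f = gates[:, H:2 * H].sigmoid()
                g = gates[:, 2 * H:3 * H].tanh()
                o = gates[:, 3 * H:4 * H].sigmoid()
                c = f * c + i * g
                h = o * c.tanh()
                outs.append(h)
            layer_input = stack(outs, axis=1)
        return layer_input


class CausalSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, pad_mask: np.ndarray | None = None) -> Tensor:
        B, T, D = x.shape
        H, hd = self.n_heads, self.head_dim
        qkv = self.qkv(x)  # (B, T, 3D)
        qkv = qkv.reshape(B, T, 3, H, hd).transpose(2, 0, 3, 1, 4)  # (3,B,H,T,hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(hd))  # (B,H,T,T)
        causal = np.triu(np.full((T, T), -1e9), k=1)
        bias = causal[None, None, :, :]
        if pad_mask is not None:
            # pad_mask: (B, T) with 1 for real tokens; block attending to pads
            bias = bias + np.where(pad_mask[:, None, None, :] > 0, 0.0, -1e9)
        att = softmax(scores + Tensor(bias), axis=-1)
        out = att @ v  # (B,H,T,hd)
        out = out.transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.proj(out)


class TransformerBlock(Module):
    def __init__(self, dim: int, n_heads: int, ff_mult: int, rng: np.random.Generator):
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = CausalSelfAttention(dim, n_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Linear(dim, ff_mult * dim, rng)
        self.fc2 = Linear(ff_mult * dim, dim, rng)

    def __call__(self, x: Tensor, pad_mask: np.ndarray | None = None) -> Tensor:
        x = x + self.attn(self.ln1(x), pad_mask)
        x = x + self.fc2(self.fc1(self.ln2(x)).relu())
        return x
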