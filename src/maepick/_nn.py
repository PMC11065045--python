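"""Transformer building blocks and an AdamW optimizer on the autodiff engine."""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, gelu, layer_norm, parameter, softmax


class Module:
    """Lightweight parameter container with named state dicts."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{key}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        bound = float(np.sqrt(6.0 / (d_in + d_out)))  # Glorot uniform
        self.weight = parameter(rng.uniform(-bound, bound, size=(d_in, d_out)))
        self.bias = parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = parameter(np.ones(dim))
        self.beta = parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class MultiheadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        h, hd = self.n_heads, self.head_dim
        qkv = self.qkv(x).reshape(b, n, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # each (b, h, n, hd)
        attn = softmax((q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd)), axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm transformer block (attention + MLP, residual connections)."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator, mlp_ratio: int = 4):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiheadSelfAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, mlp_ratio * dim, rng)
        self.fc2 = Linear(mlp_ratio * dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(gelu(self.fc1(self.norm2(x))))


def sincos_pos_embed(n_pos_per_side: int, dim: int) -> np.ndarray:
    """Fixed 2D sine-cosine positional embeddings, (n_side**2, dim)."""
    if dim % 4:
        raise ValueError("embedding dim must be divisible by 4")
    grid_y, grid_x = np.meshgrid(
        np.arange(n_pos_per_side, dtype=np.float64),
        np.arange(n_pos_per_side, dtype=np.float64),
        indexing="ij",
    )
    d4 = dim // 4
    omega = 1.0 / 10000.0 ** (np.arange(d4) / d4)
    out = []
    for grid in (grid_y, grid_x):
        phase = grid.reshape(-1, 1) * omega[None, :]
        out += [np.sin(phase), np.cos(phase)]
    return np.concatenate(out, axis=1).astype(np.float32)


class AdamW:
    """Decoupled weight-decay Adam."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            update = (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data = p.data - self.lr * update

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
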