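"""Masked autoencoder backbone.

A small ViT-style encoder/decoder pair: images are cut into square
patches, a random 75% of the patches is dropped, the encoder sees only
the visible patches, and the decoder reconstructs the full patch grid
from the encoded tokens plus a learned mask token.  The pooled encoder
output is the latent feature compared by cosine similarity downstream.

Two presets are provided: :func:`MaeConfig` defaults follow the common
224/16 ViT geometry; :func:`MaeConfig.desk_scale` is a small-capacity,
64-pixel-input variant sized for CPU experiments on 64-px particle
crops (the crops are encoded at native resolution, nothing is gained by
upsampling them).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._autodiff import as_tensor, concat, gather_tokens, no_grad, parameter
from ._nn import LayerNorm, Linear, Module, TransformerBlock, sincos_pos_embed


@dataclass
class MaeConfig:
    input_size: int = 224
    patch_size: int = 16
    mask_ratio: float = 0.75
    embed_dim: int = 64
    depth: int = 4
    n_heads: int = 4
    decoder_embed_dim: int = 32
    decoder_depth: int = 2
    pooling: str = "mean_tokens"  # or "cls_token"
    normalization: str = "mean_only"  # or "zscore", see encode()

    def __post_init__(self):
        if self.input_size % self.patch_size:
            raise ValueError(
                f"input_size {self.input_size} not divisible by patch_size {self.patch_size}")
        if not 0.0 <= self.mask_ratio < 1.0:
            raise ValueError(f"mask_ratio must be in [0, 1), got {self.mask_ratio}")
        if self.pooling not in ("mean_tokens", "cls_token"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if self.normalization not in ("mean_only", "zscore"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def n_patches_per_side(self) -> int:
        return self.input_size // self.patch_size

    @property
    def n_patches(self) -> int:
        return self.n_patches_per_side**2

    @classmethod
    def desk_scale(cls, **overrides) -> "MaeConfig":
        """Small config for CPU runs on native-resolution 64-px crops."""
        kw = dict(input_size=64, patch_size=8)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class MaskedBatch:
    """Per-image random patch masking bookkeeping.

    ``mask_index`` is True where a patch is MASKED; ``ids_keep`` lists the
    visible patch indices (in shuffled order) and ``ids_restore`` is the
    permutation that maps the [visible | masked] concatenation back to
    the original patch order.
    """

    mask_index: np.ndarray  # (B, N) bool
    ids_keep: np.ndarray  # (B, N_vis) int
    ids_restore: np.ndarray  # (B, N) int

    @property
    def n_masked(self) -> int:
        return int(self.mask_index[0].sum())


def patchify(images: np.ndarray, patch_size: int) -> np.ndarray:
    """(B, H, W) -> (B, N, patch_size**2) row-major patch sequence."""
    images = np.asarray(images)
    squeeze = images.ndim == 2
    if squeeze:
        images = images[None]
    b, h, w = images.shape
    if h % patch_size or w % patch_size:
        raise ValueError(
            f"image size {(h, w)} not divisible by patch_size {patch_size}")
    gh, gw = h // patch_size, w // patch_size
    x = images.reshape(b, gh, patch_size, gw, patch_size)
    x = x.transpose(0, 1, 3, 2, 4).reshape(b, gh * gw, patch_size**2)
    return x[0] if squeeze else x


def unpatchify(patches: np.ndarray, patch_size: int) -> np.ndarray:
    """Inverse of :func:`patchify` for square images."""
    patches = np.asarray(patches)
    squeeze = patches.ndim == 2
    if squeeze:
        patches = patches[None]
    b, n, pp = patches.shape
    g = int(round(np.sqrt(n)))
    if g * g != n or pp != patch_size**2:
        raise ValueError(f"cannot unpatchify shape {(n, pp)} with patch {patch_size}")
    x = patches.reshape(b, g, g, patch_size, patch_size)
    x = x.transpose(0, 1, 3, 2, 4).reshape(b, g * patch_size, g * patch_size)
    return x[0] if squeeze else x


def random_mask(patches, mask_ratio: float, rng: np.random.Generator | int,
                batch_size: int = 1) -> MaskedBatch:
    """Uniform without-replacement masking of ``round(mask_ratio * N)`` patches.

    ``patches`` is either the patch count N or a (B, N, p*p) patch array
    (in which case the batch size is inferred).  Deterministic for a
    fixed generator state / integer seed.
    """
    if isinstance(patches, (int, np.integer)):
        n_patches = int(patches)
    else:
        arr = np.asarray(patches)
        if arr.ndim != 3:
            raise ValueError("patch array must be (batch, n_patches, patch_pixels)")
        batch_size, n_patches = arr.shape[0], arr.shape[1]
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if not 0.0 <= mask_ratio < 1.0:
        raise ValueError(f"mask_ratio must be in [0, 1), got {mask_ratio}")
    n_mask = int(round(mask_ratio * n_patches))
    n_keep = n_patches - n_mask
    if n_mask == 0:
        ids = np.tile(np.arange(n_patches), (batch_size, 1))
        return MaskedBatch(np.zeros((batch_size, n_patches), bool), ids, ids.copy())
    noise = rng.random((batch_size, n_patches))
    shuffle = np.argsort(noise, axis=1)  # ascending: first n_keep are visible
    ids_keep = shuffle[:, :n_keep]
    ids_restore = np.argsort(shuffle, axis=1)
    mask = np.ones((batch_size, n_patches), dtype=bool)
    np.put_along_axis(mask, ids_keep, False, axis=1)
    return MaskedBatch(mask, ids_keep, ids_restore)


def zscore(images: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Per-image zero-mean unit-variance normalization."""
    images = np.asarray(images, dtype=np.float32)
    axes = tuple(range(1, images.ndim)) if images.ndim > 2 else None
    mu = images.mean(axis=axes, keepdims=images.ndim > 2)
    sd = images.std(axis=axes, keepdims=images.ndim > 2)
    return (images - mu) / (sd + eps)


def demean(images: np.ndarray) -> np.ndarray:
    """Per-image mean removal (amplitude is preserved).

    Used with micrograph-level contrast scaling (see
    :func:`maepick.train.contrast_scale`): removing the local mean
    discards illumination offsets while keeping the local signal
    amplitude, which separates structured particle crops from flat
    noise — information that per-crop variance scaling would erase.
    """
    images = np.asarray(images, dtype=np.float32)
    axes = tuple(range(1, images.ndim)) if images.ndim > 2 else None
    return images - images.mean(axis=axes, keepdims=images.ndim > 2)


class MaskedAutoencoder(Module):
    """ViT-MAE with fixed sin-cos positional embeddings."""

    def __init__(self, cfg: MaeConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        p2 = cfg.patch_size**2
        self.patch_embed = Linear(p2, cfg.embed_dim, rng)
        self.blocks = [TransformerBlock(cfg.embed_dim, cfg.n_heads, rng)
                       for _ in range(cfg.depth)]
        self.norm = LayerNorm(cfg.embed_dim)
        self.cls_token = parameter(0.02 * rng.standard_normal((1, 1, cfg.embed_dim)))
        self.decoder_embed = Linear(cfg.embed_dim, cfg.decoder_embed_dim, rng)
        self.mask_token = parameter(0.02 * rng.standard_normal((1, 1, cfg.decoder_embed_dim)))
        self.decoder_blocks = [TransformerBlock(cfg.decoder_embed_dim, cfg.n_heads, rng)
                               for _ in range(cfg.decoder_depth)]
        self.decoder_norm = LayerNorm(cfg.decoder_embed_dim)
        self.decoder_pred = Linear(cfg.decoder_embed_dim, p2, rng)
        self.pos_embed = sincos_pos_embed(cfg.n_patches_per_side, cfg.embed_dim)
        self.decoder_pos_embed = sincos_pos_embed(cfg.n_patches_per_side,
                                                  cfg.decoder_embed_dim)

    # ------------------------------------------------------------------
    def encode(self, images: np.ndarray, mask: MaskedBatch | None = None):
        """Encode (a batch of) images into tokens and a pooled latent.

        With ``mask`` given, only visible patches are processed (stage-1
        training); without it all patches contribute (stage-2 scanning).
        Returns ``(tokens, latent)`` as autodiff Tensors; ``latent`` is
        (B, embed_dim) pooled per ``cfg.pooling``.
        """
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 2:
            images = images[None]
        s = self.cfg.input_size
        if images.shape[-2:] != (s, s):
            raise ValueError(
                f"expected {s}x{s} input images, got {images.shape[-2:]}")
        norm = zscore if self.cfg.normalization == "zscore" else demean
        patches = patchify(norm(images), self.cfg.patch_size)
        b = patches.shape[0]
        if mask is not None:
            b_idx = np.arange(b)[:, None]
            patches = patches[b_idx, mask.ids_keep]
            pos = self.pos_embed[mask.ids_keep]  # (B, N_vis, D)
        else:
            pos = np.broadcast_to(self.pos_embed, (b, *self.pos_embed.shape))
        x = self.patch_embed(as_tensor(patches)) + as_tensor(pos)
        if self.cfg.pooling == "cls_token":
            cls = self.cls_token + as_tensor(np.zeros((b, 1, self.cfg.embed_dim),
                                                      np.float32))
            x = concat([cls, x], axis=1)
        for blk in self.blocks:
            x = blk(x)
        x = self.norm(x)
        if self.cfg.pooling == "cls_token":
            latent = x[:, 0]
            tokens = x[:, 1:]
        else:
            tokens = x
            latent = x.mean(axis=1)
        return tokens, latent

    def decode(self, tokens, mask: MaskedBatch):
        """Reconstruct the full patch grid from visible-token encodings."""
        x = self.decoder_embed(tokens)
        b, n_vis, dd = x.shape
        n = self.cfg.n_patches
        mask_tokens = self.mask_token + as_tensor(
            np.zeros((b, n - n_vis, dd), np.float32))
        x = concat([x, mask_tokens], axis=1)
        x = gather_tokens(x, mask.ids_restore)
        x = x + as_tensor(np.broadcast_to(self.decoder_pos_embed,
                                          (b, *self.decoder_pos_embed.shape)))
        for blk in self.decoder_blocks:
            x = blk(x)
        return self.decoder_pred(self.decoder_norm(x))

    def forward_loss(self, images: np.ndarray, mask: MaskedBatch):
        """Full masked forward pass: returns (loss, latent, pred)."""
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 2:
            images = images[None]
        tokens, latent = self.encode(images, mask)
        pred = self.decode(tokens, mask)
        norm = zscore if self.cfg.normalization == "zscore" else demean
        target = patchify(norm(images), self.cfg.patch_size)
        loss = mse_loss(pred, target, mask)
        return loss, latent, pred

    def embed(self, images: np.ndarray) -> np.ndarray:
        """Pooled latent features without masking or gradients, (B, D)."""
        with no_grad():
            _, latent = self.encode(images)
        return latent.data

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        """Save weights + config as a single .npz archive."""
        path = Path(path)
        if path.suffix != ".npz":
            path = Path(str(path) + ".npz")
        np.savez(path, __config__=json.dumps(asdict(self.cfg)),
                 **self.state_dict())
        return path

    @classmethod
    def load(cls, path: str | Path) -> "MaskedAutoencoder":
        with np.load(Path(path), allow_pickle=False) as archive:
            cfg = MaeConfig(**json.loads(str(archive["__config__"])))
            state = {k: archive[k] for k in archive.files if k != "__config__"}
        model = cls(cfg)
        model.load_state_dict(state)
        return model


def mse_loss(pred, target: np.ndarray, mask: MaskedBatch):
    """Mean squared reconstruction error over MASKED patches only."""
    target_t = as_tensor(np.asarray(target, dtype=np.float32))
    diff = pred - target_t
    m = mask.mask_index.astype(np.float32)[:, :, None]  # (B, N, 1)
    denom = float(m.sum() * target_t.shape[-1])
    if denom == 0:
        denom = float(np.prod(target_t.shape))
        m = np.ones_like(m)
    return (diff * diff * as_tensor(m)).sum() * (1.0 / denom)
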