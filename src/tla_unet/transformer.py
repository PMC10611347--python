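"""Transformer bottleneck and the spatial coefficient map ``Ws``.

The bottleneck feature plane is cut into square patches, linearly projected
to a token sequence with learned position embeddings, and run through a
stack of pre-norm multi-head self-attention layers. Two things come back
out: the transformed tokens (reshaped to a grid and projected for the
decoder) and the final layer's attention matrices, which are reduced to a
single-channel spatial coefficient map in [0, 1] that the TLA decoder blocks
multiply into their features.

Because a softmax attention matrix has token-by-token shape rather than a
spatial one, the coefficient map is built by averaging each token's
*received* attention mass over heads and query tokens (column mean),
reshaping to the patch grid, min-max normalising and bilinearly upsampling.
Constant (uninformative) attention degrades gracefully to an all-ones map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, as_tensor, bilinear_matrix
from .nn import LayerNorm, Linear, Module, Parameter

__all__ = [
    "TransformerConfig",
    "PatchEmbed",
    "SelfAttentionLayer",
    "TransformerEncoder",
    "spatial_coefficient_map",
    "TokensToGrid",
]


@dataclass(frozen=True)
class TransformerConfig:
    """Scale of the bottleneck Transformer.

    ``base`` scale: hidden 768, 12 layers, MLP 3072, 12 heads.
    ``large`` scale: hidden 1024, 24 layers, MLP 4096, 16 heads.
    """

    patch_size: int = 16
    hidden_size: int = 768
    n_layers: int = 12
    mlp_size: int = 3072
    n_heads: int = 12

    def __post_init__(self):
        for field in ("patch_size", "hidden_size", "n_layers", "mlp_size", "n_heads"):
            if getattr(self, field) < 0 or (field != "n_layers" and getattr(self, field) < 1):
                raise ValueError(f"{field} must be positive, got {getattr(self, field)}")
        if self.hidden_size % self.n_heads:
            raise ValueError(
                f"hidden_size {self.hidden_size} not divisible by "
                f"n_heads {self.n_heads}")

    @classmethod
    def scale(cls, name: str, patch_size: int = 16) -> "TransformerConfig":
        presets = {
            "base": dict(hidden_size=768, n_layers=12, mlp_size=3072, n_heads=12),
            "large": dict(hidden_size=1024, n_layers=24, mlp_size=4096, n_heads=16),
        }
        if name not in presets:
            raise ValueError(f"unknown scale {name!r}; choose from {sorted(presets)}")
        return cls(patch_size=patch_size, **presets[name])


class PatchEmbed(Module):
    """Linear patch projection plus learned 1D position embeddings."""

    def __init__(self, in_channels: int, plane_hw: tuple[int, int],
                 cfg: TransformerConfig, rng: np.random.Generator):
        super().__init__()
        ps = cfg.patch_size
        h, w = plane_hw
        if h % ps or w % ps:
            raise ValueError(
                f"patch size {ps} does not divide feature plane {h}x{w}")
        self.patch_size = ps
        self.grid_shape = (h // ps, w // ps)
        n_tokens = self.grid_shape[0] * self.grid_shape[1]
        self.proj = Linear(in_channels * ps * ps, cfg.hidden_size, rng)
        self.pos = Parameter(rng.normal(0.0, 0.02, size=(n_tokens, cfg.hidden_size)))

    def __call__(self, x: Tensor) -> Tensor:
        """(N, C, H, W) -> (N, n_tokens, hidden); row-major patch order."""
        x = as_tensor(x)
        n, c, h, w = x.shape
        ps = self.patch_size
        gh, gw = self.grid_shape
        patches = (x.reshape(n, c, gh, ps, gw, ps)
                    .transpose(0, 2, 4, 1, 3, 5)
                    .reshape(n, gh * gw, c * ps * ps))
        return self.proj(patches) + self.pos


class SelfAttentionLayer(Module):
    """Pre-norm Transformer layer: MHSA + MLP, both with residuals."""

    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.hidden_size
        self.n_heads = cfg.n_heads
        self.head_dim = d // cfg.n_heads
        self.norm1 = LayerNorm(d)
        self.q = Linear(d, d, rng)
        self.k = Linear(d, d, rng)
        self.v = Linear(d, d, rng)
        self.out = Linear(d, d, rng)
        self.norm2 = LayerNorm(d)
        self.mlp1 = Linear(d, cfg.mlp_size, rng)
        self.mlp2 = Linear(cfg.mlp_size, d, rng)

    def __call__(self, seq: Tensor) -> tuple[Tensor, np.ndarray]:
        seq = as_tensor(seq)
        n, t, d = seq.shape
        h, hd = self.n_heads, self.head_dim

        x = self.norm1(seq)

        def split_heads(lin):
            return lin(x).reshape(n, t, h, hd).transpose(0, 2, 1, 3)

        q, k, v = split_heads(self.q), split_heads(self.k), split_heads(self.v)
        scores = q.matmul(k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        attn = scores.softmax(axis=-1)            # (N, heads, T, T)
        ctx = attn.matmul(v).transpose(0, 2, 1, 3).reshape(n, t, d)
        seq = seq + self.out(ctx)
        seq = seq + self.mlp2(self.mlp1(self.norm2(seq)).gelu())
        return seq, attn.data.copy()


class TransformerEncoder(Module):
    """Stack of self-attention layers; also reports the final attention."""

    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        super().__init__()
        self.layers = [SelfAttentionLayer(cfg, rng) for _ in range(cfg.n_layers)]

    def __call__(self, seq: Tensor) -> tuple[Tensor, np.ndarray | None]:
        seq = as_tensor(seq)
        attn = None
        for layer in self.layers:
            seq, attn = layer(seq)
        return seq, attn


def spatial_coefficient_map(attn: np.ndarray, grid_shape: tuple[int, int],
                            target_hw: tuple[int, int]) -> np.ndarray:
    """Reduce final-layer attention to a (1, H, W) coefficient map in [0, 1].

    ``attn`` has shape (heads, T, T) or (N, heads, T, T); the per-token score
    is the mean attention the token receives (mean over heads and query
    rows), min-max normalised on the patch grid then bilinearly resampled.
    A constant reduction (e.g. uniform attention) falls back to all-ones.
    """
    attn = np.asarray(attn, dtype=np.float64)
    batched = attn.ndim == 4
    if not batched:
        attn = attn[None]
    n, _, t, t2 = attn.shape
    gh, gw = grid_shape
    if t != t2 or t != gh * gw:
        raise ValueError(
            f"attention of {t} tokens does not match grid {gh}x{gw}")
    received = attn.mean(axis=(1, 2))             # (N, T) column means
    grid = received.reshape(n, 1, gh, gw)
    lo = grid.min(axis=(2, 3), keepdims=True)
    hi = grid.max(axis=(2, 3), keepdims=True)
    span = hi - lo
    norm = np.where(span > 1e-12, (grid - lo) / np.where(span > 0, span, 1.0), 1.0)
    a = bilinear_matrix(gh, target_hw[0])
    b = bilinear_matrix(gw, target_hw[1])
    ws = np.clip(np.matmul(np.matmul(a, norm), b.T), 0.0, 1.0)
    return ws if batched else ws[0]


class TokensToGrid(Module):
    """Reshape tokens to their grid and 1x1-project to a decoder width.

    Token ``i`` maps to grid cell ``(i // w, i % w)``, inverse to the patch
    order of :class:`PatchEmbed`.
    """

    def __init__(self, hidden_size: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.proj = Linear(hidden_size, out_channels, rng)

    def __call__(self, seq: Tensor, grid_shape: tuple[int, int]) -> Tensor:
        seq = as_tensor(seq)
        n, t, d = seq.shape
        gh, gw = grid_shape
        if t != gh * gw:
            raise ValueError(f"{t} tokens do not fill a {gh}x{gw} grid")
        projected = self.proj(seq)                # (N, T, out)
        return projected.transpose(0, 2, 1).reshape(n, -1, gh, gw)
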