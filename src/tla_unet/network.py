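"""Full segmentation network: CNN encoder, Transformer bottleneck, UNet++
dense decoder with TLA blocks, SE-augmented skips and deep-supervision heads.

Architecture sketch (depth ``d``, base width ``w``)::

    image -> [DoubleConv + SE?] x d  (skips, widths w, 2w, ..., 2^(d-1) w)
          -> maxpool -> patch embed -> Transformer -> tokens_to_grid = Z
    decoder: UNet++ lattice X(i, j); X(i, 0) are the skips, the level-d
    predecessor is Z. Node X(i, j) concatenates X(i, 0..j-1) with the
    upsampled X(i+1, j-1) and applies a double conv; the outermost node of
    each level (j = d - i) is a TLA block when enabled.
    Heads: 1x1 main head on X(0, d); one side head per outermost node
    (upsampled to input size, training-time supervision only); aux heads on
    the intermediate top-row nodes X(0, 1..d-1).

The Transformer's final-layer attention is reduced to the spatial
coefficient map ``Ws`` which the TLA blocks multiply into their output.
Ablation switches (``use_unetpp``, ``use_side_outputs``, ``use_tla``,
``use_se``) reduce the network to the corresponding simpler architecture;
with all of them off the forward pass is exactly a plain UNet with a
Transformer bottleneck.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autograd import Tensor, as_tensor, concat
from .nn import Conv2d, DoubleConv, Module
from .blocks import SqueezeExcitation, TLABlock
from .transformer import (PatchEmbed, TokensToGrid, TransformerConfig,
                          TransformerEncoder, spatial_coefficient_map)

__all__ = ["ModelConfig", "ModelOutput", "TLAUNet", "build_model", "desk_scale_config"]


@dataclass(frozen=True)
class ModelConfig:
    """All architecture hyperparameters and ablation switches."""

    n_classes: int = 9
    in_channels: int = 1
    input_size: int = 224
    depth: int = 4
    base_width: int = 64
    transformer: TransformerConfig = field(default_factory=TransformerConfig)
    token_plane: str = "bottleneck"   # "bottleneck" (hybrid) or "image"
    use_unetpp: bool = True
    use_side_outputs: bool = True
    use_tla: bool = True
    use_se: bool = True
    se_reduction: int = 16
    attention_reduction: int = 16
    deep_supervision_weights: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        stride = 2 ** self.depth
        if self.input_size % stride:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth = {stride}")
        ps = self.transformer.patch_size
        if self.input_size % ps:
            raise ValueError(
                f"input_size {self.input_size} not divisible by patch size {ps}")
        if self.token_plane == "bottleneck":
            if ps % stride:
                raise ValueError(
                    f"patch size {ps} must be a multiple of 2^depth = {stride} "
                    "to patch the bottleneck plane")
        elif self.token_plane != "image":
            raise ValueError(f"token_plane must be 'bottleneck' or 'image', "
                             f"got {self.token_plane!r}")

    @property
    def n_tokens(self) -> int:
        return (self.input_size // self.transformer.patch_size) ** 2

    @property
    def grid_shape(self) -> tuple[int, int]:
        g = self.input_size // self.transformer.patch_size
        return (g, g)

    @property
    def bottleneck_hw(self) -> tuple[int, int]:
        s = self.input_size // 2 ** self.depth
        return (s, s)

    @property
    def widths(self) -> tuple[int, ...]:
        return tuple(self.base_width * 2 ** i for i in range(self.depth))


def desk_scale_config(n_classes: int = 4, **overrides) -> ModelConfig:
    """Desk-scale configuration every test runs at: 64x64 input, hidden 64,
    2 Transformer layers, MLP 128, 4 heads, patch 4."""
    cfg = ModelConfig(
        n_classes=n_classes,
        input_size=64,
        depth=2,
        base_width=16,
        transformer=TransformerConfig(patch_size=4, hidden_size=64,
                                      n_layers=2, mlp_size=128, n_heads=4),
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class ModelOutput:
    """Per-pixel logits of the main head plus training-time auxiliaries."""

    main_logits: Tensor
    side_logits: list[Tensor]
    aux_node_logits: list[Tensor]

    def all_outputs(self) -> list[Tensor]:
        return [self.main_logits, *self.side_logits, *self.aux_node_logits]

    def probabilities(self) -> np.ndarray:
        return self.main_logits.softmax(axis=1).data

    def predictions(self) -> np.ndarray:
        """Per-pixel argmax class labels; ties resolve to the lowest index."""
        return np.argmax(self.main_logits.data, axis=1)


class Encoder(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.stages = []
        in_ch = cfg.in_channels
        for w in cfg.widths:
            self.stages.append(DoubleConv(in_ch, w, rng))
            in_ch = w
        self.se = None
        if cfg.use_se:
            self.se = [SqueezeExcitation(w, rng, int(np.gcd(w, cfg.se_reduction)))
                       for w in cfg.widths]

    def __call__(self, x: Tensor) -> tuple[list[Tensor], Tensor]:
        skips = []
        for i, stage in enumerate(self.stages):
            x = stage(x)
            skips.append(self.se[i](x) if self.se is not None else x)
            x = x.maxpool2x2()
        return skips, x       # x is the pooled bottleneck plane


class TLAUNet(Module):
    """The assembled model. Construct via :func:`build_model`."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d = cfg.depth
        widths = cfg.widths
        bottleneck_w = widths[-1]

        self.encoder = Encoder(cfg, rng)
        if cfg.token_plane == "bottleneck":
            plane_hw = cfg.bottleneck_hw
            plane_ch = widths[-1]
            patch_cfg = replace(cfg.transformer,
                                patch_size=cfg.transformer.patch_size // 2 ** d)
        else:
            plane_hw = (cfg.input_size, cfg.input_size)
            plane_ch = cfg.in_channels
            patch_cfg = cfg.transformer
        self.patch_embed = PatchEmbed(plane_ch, plane_hw, patch_cfg, rng)
        self.transformer = TransformerEncoder(cfg.transformer, rng)
        self.tokens_to_grid = TokensToGrid(cfg.transformer.hidden_size,
                                           bottleneck_w, rng)

        # decoder lattice: dict keyed by (level, node index j >= 1)
        self.nodes: dict[tuple[int, int], Module] = {}
        for i in range(d):
            j_max = (d - i) if cfg.use_unetpp else 1
            for j in range(1, j_max + 1):
                # predecessors X(i, 0..j-1) all have width w_i; the deeper
                # input X(i+1, j-1) is an encoder skip for j == 1 at the
                # deepest level the Transformer grid, else a decoder node
                skip_w = widths[i]
                gate_w = bottleneck_w if i + 1 == d else widths[i + 1]
                extra_w = (j - 1) * widths[i]
                outermost = j == j_max
                if cfg.use_tla and outermost:
                    self.nodes[(i, j)] = TLABlock(
                        skip_w, gate_w, widths[i], rng,
                        extra_channels=extra_w,
                        reduction=cfg.attention_reduction)
                else:
                    self.nodes[(i, j)] = DoubleConv(
                        skip_w + extra_w + gate_w, widths[i], rng)
        self._node_list = [self.nodes[k] for k in sorted(self.nodes)]

        self.main_head = Conv2d(widths[0], cfg.n_classes, 1, rng)
        self.side_heads = None
        if cfg.use_side_outputs:
            j_max = lambda i: (d - i) if cfg.use_unetpp else 1
            self.side_heads = [Conv2d(widths[i], cfg.n_classes, 1, rng)
                               for i in range(d)]
        self.aux_heads = None
        if cfg.use_unetpp:
            self.aux_heads = [Conv2d(widths[0], cfg.n_classes, 1, rng)
                              for _ in range(d - 1)]

    # -- forward -------------------------------------------------------------
    def __call__(self, image) -> ModelOutput:
        cfg = self.cfg
        x = as_tensor(image)
        if x.ndim == 3:
            x = x.reshape((1, *x.shape))
        n, c, h, w = x.shape
        if (h, w) != (cfg.input_size, cfg.input_size) or c != cfg.in_channels:
            raise ValueError(
                f"expected ({cfg.in_channels}, {cfg.input_size}, "
                f"{cfg.input_size}) input, got ({c}, {h}, {w})")

        skips, bottleneck = self.encoder(x)
        plane = bottleneck if cfg.token_plane == "bottleneck" else x
        tokens = self.patch_embed(plane)
        tokens, attn = self.transformer(tokens)
        grid = self.patch_embed.grid_shape
        z = self.tokens_to_grid(tokens, grid)
        if grid != cfg.bottleneck_hw:
            z = z.bilinear_resize(cfg.bottleneck_hw)
        if attn is not None:
            ws = Tensor(spatial_coefficient_map(attn, grid, cfg.bottleneck_hw)
                        .astype(x.data.dtype))
        else:  # zero-layer Transformer: neutral coefficients
            ws = Tensor(np.ones((n, 1, *cfg.bottleneck_hw), dtype=x.data.dtype))
        return self._decode(skips, z, ws)

    def _decode(self, skips: list[Tensor], z: Tensor, ws: Tensor) -> ModelOutput:
        cfg = self.cfg
        d = cfg.depth
        computed: dict[tuple[int, int], Tensor] = {
            (i, 0): s for i, s in enumerate(skips)}

        def deeper_of(i: int, j: int) -> Tensor:
            if i + 1 == d:
                return z
            # dense lattice: X(i+1, j-1); plain UNet: the decoder node below
            return computed[(i + 1, j - 1 if cfg.use_unetpp else 1)]

        j_max = lambda i: (d - i) if cfg.use_unetpp else 1

        for i in range(d - 1, -1, -1):
            for j in range(1, j_max(i) + 1):
                deeper = deeper_of(i, j)
                target_hw = computed[(i, 0)].shape[-2:]
                node = self.nodes[(i, j)]
                extras = [computed[(i, jj)] for jj in range(1, j)]
                if isinstance(node, TLABlock):
                    computed[(i, j)] = node(computed[(i, 0)], deeper, ws,
                                            extras=tuple(extras))
                else:
                    up = deeper.bilinear_resize(target_hw)
                    computed[(i, j)] = node(
                        concat([computed[(i, 0)], *extras, up], axis=1))

        final = computed[(0, j_max(0))]
        main = self.main_head(final)
        full_hw = main.shape[-2:]
        side = []
        if self.side_heads is not None:
            for i in range(d):
                feat = computed[(i, j_max(i))]
                side.append(self.side_heads[i](feat).bilinear_resize(full_hw))
        aux = []
        if self.aux_heads is not None:
            for j in range(1, d):
                aux.append(self.aux_heads[j - 1](computed[(0, j)]))
        return ModelOutput(main, side, aux)

    # -- introspection -------------------------------------------------------
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def build_model(cfg: ModelConfig) -> TLAUNet:
    """Validate the configuration eagerly and construct the model."""
    model = TLAUNet(cfg)
    return model
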