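"""Attention building blocks and their composition into the TLA module.

Three attention mechanisms are combined in the decoder:

* **Attention Gate (AG)** — a coarse gating signal ``z`` suppresses
  skip-connection features ``x`` in irrelevant regions:
  ``sigma(phi(ReLU(theta_x(x) + theta_z(z)))) * x`` with 1x1 channelwise
  projections and a single-channel sigmoid coefficient broadcast over ``x``.
* **Channel attention** — global average- and max-pooled channel vectors run
  through a shared two-layer perceptron; the sigmoid of their sum rescales
  each channel.
* **Squeeze-and-Excitation (SE)** — channel recalibration on encoder skips:
  global average pool, bottleneck perceptron (ReLU then sigmoid), per-channel
  rescale.

The **Three-Level Attention (TLA)** block chains, in order: attention gate on
the skip features, concatenation with the upsampled decoder feature (plus any
dense-lattice predecessors), channel attention, two conv+ReLU layers closed
by batch normalization, and finally elementwise multiplication by the
Transformer-derived spatial coefficient map ``Ws``.

Each block is a :class:`~tla_unet.nn.Module` operating on batched
``(N, C, H, W)`` tensors; thin functional wrappers at the bottom of the file
apply a block to a single unbatched ``(C, H, W)`` array.

Gates are initialised *open*: the bias feeding each final sigmoid starts at
+3, so every attention coefficient begins near 0.95 and the untrained
network behaves like its gate-free counterpart. Random closed gates
(coefficients near 0.5 or below) multiplicatively attenuate both features
and gradients and visibly slow early SGD progress; open-gate starts are the
gated-architecture analogue of identity-biased residual initialisation.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor, concat
from .nn import BatchNorm2d, Conv2d, DoubleConv, Linear, Module

GATE_OPEN_BIAS = 3.0   # initial bias of every gate's final sigmoid

__all__ = [
    "AttentionGate",
    "ChannelAttention",
    "SqueezeExcitation",
    "TLABlock",
    "attention_gate",
    "channel_attention",
    "squeeze_excitation",
    "apply_spatial_coefficients",
    "tla_block",
]


def _check_resampleable(x_hw: tuple[int, int], z_hw: tuple[int, int]) -> None:
    """The gating signal may only be coarser by an integer factor."""
    (xh, xw), (zh, zw) = x_hw, z_hw
    if (xh, xw) == (zh, zw):
        return
    if zh > xh or zw > xw or xh % zh or xw % zw:
        raise ValueError(
            f"gating signal {zh}x{zw} is not an integer-ratio downsample of "
            f"skip features {xh}x{xw}")


class AttentionGate(Module):
    """Additive attention gate with 1x1 projections.

    The intermediate width is ``min(C_x, C_z)``. A gating signal at a coarser
    resolution is bilinearly upsampled (after projection) to the skip
    features' grid.
    """

    def __init__(self, x_channels: int, z_channels: int, rng: np.random.Generator):
        super().__init__()
        inter = min(x_channels, z_channels)
        self.theta_x = Conv2d(x_channels, inter, 1, rng)
        self.theta_z = Conv2d(z_channels, inter, 1, rng)
        self.phi = Conv2d(inter, 1, 1, rng)
        self.phi.bias.data[:] = GATE_OPEN_BIAS

    def __call__(self, x: Tensor, z: Tensor) -> Tensor:
        x, z = as_tensor(x), as_tensor(z)
        _check_resampleable(x.shape[-2:], z.shape[-2:])
        tz = self.theta_z(z).bilinear_resize(x.shape[-2:])
        coeff = self.phi((self.theta_x(x) + tz).relu()).sigmoid()
        return x * coeff


class ChannelAttention(Module):
    """CBAM-style channel attention: sigma(MLP(avg) + MLP(max)) per channel."""

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 16):
        super().__init__()
        if channels % reduction:
            raise ValueError(
                f"reduction ratio {reduction} does not divide {channels} channels")
        self.fc1 = Linear(channels, channels // reduction, rng)
        self.fc2 = Linear(channels // reduction, channels, rng)
        self.fc2.bias.data[:] = GATE_OPEN_BIAS   # both MLP passes carry it

    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc2(self.fc1(v).relu())

    def __call__(self, f: Tensor) -> Tensor:
        f = as_tensor(f)
        if not np.all(np.isfinite(f.data)):
            raise ValueError("channel attention received non-finite input")
        n, c = f.shape[0], f.shape[1]
        avg = f.mean(axis=(2, 3))                 # (N, C) global average pool
        mx = f.reshape(n, c, -1).max_reduce(axis=2)
        scale = (self._mlp(avg) + self._mlp(mx)).sigmoid()
        return f * scale.reshape(n, c, 1, 1)


class SqueezeExcitation(Module):
    """Standard SE block: squeeze (global average) then excite (bottleneck MLP)."""

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 16):
        super().__init__()
        if channels % reduction:
            raise ValueError(
                f"reduction ratio {reduction} does not divide {channels} channels")
        self.fc1 = Linear(channels, channels // reduction, rng)
        self.fc2 = Linear(channels // reduction, channels, rng)
        self.fc2.bias.data[:] = GATE_OPEN_BIAS

    def __call__(self, f: Tensor) -> Tensor:
        f = as_tensor(f)
        n, c = f.shape[0], f.shape[1]
        squeezed = f.mean(axis=(2, 3))
        scale = self.fc2(self.fc1(squeezed).relu()).sigmoid()
        return f * scale.reshape(n, c, 1, 1)


def _apply_ws(fz: Tensor, ws: Tensor) -> Tensor:
    fz, ws = as_tensor(fz), as_tensor(ws)
    if ws.shape[-3] != 1:
        raise ValueError(f"spatial coefficient map must have 1 channel, got {ws.shape}")
    if ws.shape[-2:] != fz.shape[-2:]:
        raise ValueError(
            f"spatial coefficient map {ws.shape[-2:]} does not match features "
            f"{fz.shape[-2:]}")
    return fz * ws


class TLABlock(Module):
    """Three-Level Attention decoder block.

    Forward order: (1) attention gate on the skip features using the deeper
    decoder feature as gating signal; (2) concatenation of the gated skip,
    any dense-lattice predecessors, and the bilinearly upsampled gating
    feature; (3) channel attention over the concatenation; (4) double
    conv+ReLU closed by batch norm, projecting to ``out_channels``;
    (5) elementwise multiplication with ``Ws`` resampled to this resolution.
    """

    def __init__(self, skip_channels: int, gate_channels: int, out_channels: int,
                 rng: np.random.Generator, extra_channels: int = 0,
                 reduction: int = 16):
        super().__init__()
        cat_channels = skip_channels + gate_channels + extra_channels
        reduction = int(np.gcd(cat_channels, reduction))
        self.ag = AttentionGate(skip_channels, gate_channels, rng)
        self.ca = ChannelAttention(cat_channels, rng, reduction)
        self.conv = DoubleConv(cat_channels, out_channels, rng)

    def __call__(self, skip: Tensor, gating: Tensor, ws: Tensor,
                 extras: tuple[Tensor, ...] = ()) -> Tensor:
        skip, gating = as_tensor(skip), as_tensor(gating)
        target_hw = skip.shape[-2:]
        gated = self.ag(skip, gating)
        up = gating.bilinear_resize(target_hw)
        cat = concat([gated, *map(as_tensor, extras), up], axis=1)
        attended = self.ca(cat)
        fz = self.conv(attended)
        ws = as_tensor(ws).bilinear_resize(target_hw)
        return _apply_ws(fz, ws)


# ---------------------------------------------------------------------------
# Functional single-sample wrappers: (C, H, W) ndarray in, ndarray out.


def _unbatched(module_call, *arrays):
    tensors = [as_tensor(a).reshape((1, *np.shape(a))) for a in arrays]
    out = module_call(*tensors)
    return out.data[0]


def attention_gate(x: np.ndarray, z: np.ndarray, params: AttentionGate) -> np.ndarray:
    """Gate skip features ``x`` (C, H, W) by a coarser signal ``z``."""
    params.eval()
    return _unbatched(params, x, z)


def channel_attention(f: np.ndarray, params: ChannelAttention) -> np.ndarray:
    params.eval()
    return _unbatched(params, f)


def squeeze_excitation(f: np.ndarray, params: SqueezeExcitation) -> np.ndarray:
    params.eval()
    return _unbatched(params, f)


def apply_spatial_coefficients(fz: np.ndarray, ws: np.ndarray) -> np.ndarray:
    """Multiply features (C, H, W) by a single-channel map (1, H, W)."""
    fz_t = as_tensor(fz).reshape((1, *np.shape(fz)))
    return _apply_ws(fz_t, as_tensor(ws)).data[0]


def tla_block(skip: np.ndarray, gating: np.ndarray, ws: np.ndarray,
              params: TLABlock) -> np.ndarray:
    params.eval()
    skip_t = as_tensor(skip).reshape((1, *np.shape(skip)))
    gating_t = as_tensor(gating).reshape((1, *np.shape(gating)))
    return params(skip_t, gating_t, as_tensor(ws)).data[0]
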