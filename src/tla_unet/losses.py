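"""Compound segmentation objective and deep-supervision aggregation.

The training loss is a weighted sum of a multiclass Dice loss and pixelwise
cross-entropy::

    L_total = lambda1 * L_Dice + lambda2 * L_CE          (both default 0.5)

    L_CE(u, y)   = -(1/N) sum_c sum_i u_ic log y_ic
    L_Dice(u, y) = 1 - 2 sum_c sum_i u_ic y_ic /
                       (sum_c sum_i u_ic + sum_c sum_i y_ic)

where ``u`` are one-hot ground-truth indicators, ``y`` predicted class
probabilities, ``C`` classes (background included in the Dice sums) and
``N`` pixels. Probabilities are clamped to ``[1e-7, 1]`` inside the log and
the Dice ratio is smoothed with ``1e-5`` in numerator and denominator.

Deep supervision averages the compound loss over the main output, the
decoder side-outputs and the UNet++ intermediate outputs (uniform weights by
default). Inputs may be NumPy arrays (evaluation) or autograd tensors
(training); outputs follow suit.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor, stack_mean

__all__ = [
    "cross_entropy_loss",
    "dice_loss",
    "compound_loss",
    "deep_supervision_loss",
    "one_hot",
]

LOG_EPS = 1e-7
DICE_EPS = 1e-5


def one_hot(mask: np.ndarray, n_classes: int) -> np.ndarray:
    """Integer mask (..., H, W) -> one-hot (..., C, H, W) float array."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() >= n_classes:
        raise ValueError(
            f"mask labels [{mask.min()}, {mask.max()}] exceed {n_classes} classes")
    eye = np.eye(n_classes)
    out = eye[mask.astype(int)]                    # (..., H, W, C)
    return np.moveaxis(out, -1, mask.ndim - 2)


def _check_pair(u, y) -> tuple[Tensor, Tensor]:
    u, y = as_tensor(u), as_tensor(y)
    if u.shape != y.shape:
        raise ValueError(f"shape mismatch: truth {u.shape} vs prediction {y.shape}")
    return u, y


def _maybe_item(value: Tensor, inputs) -> Tensor | float:
    if any(isinstance(v, Tensor) and v.requires_grad for v in inputs):
        return value
    return value.item()


def cross_entropy_loss(u, y):
    """Mean negative log-likelihood per pixel; >= 0."""
    ut, yt = _check_pair(u, y)
    # class axis: 0 for (C, N) / (C, H, W) layouts, 1 for batched (N, C, H, W)
    class_axis = 0 if ut.ndim <= 3 else 1
    n = ut.data.size // ut.shape[class_axis]
    total = -(ut * yt.clip(LOG_EPS, 1.0).log()).sum()
    return _maybe_item(total * (1.0 / n), (u, y))


def dice_loss(u, y):
    """Multiclass soft Dice loss in [0, 1]; background class included."""
    ut, yt = _check_pair(u, y)
    intersection = (ut * yt).sum()
    denom = ut.sum() + yt.sum()
    dice = (intersection * 2.0 + DICE_EPS) / (denom + DICE_EPS)
    return _maybe_item(1.0 - dice, (u, y))


def compound_loss(u, y, lambda1: float = 0.5, lambda2: float = 0.5):
    """lambda1 * Dice + lambda2 * cross-entropy (defaults 0.5 / 0.5)."""
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError(f"loss weights must be >= 0, got {lambda1}, {lambda2}")
    ut, yt = _check_pair(u, y)
    value = as_tensor(dice_loss(ut, yt)) * lambda1 \
        + as_tensor(cross_entropy_loss(ut, yt)) * lambda2
    return _maybe_item(value, (u, y))


def deep_supervision_loss(outputs, u, lambda1: float = 0.5, lambda2: float = 0.5,
                          weights=None):
    """Weighted mean of the compound loss over all supervised outputs.

    ``outputs`` is a ModelOutput or a list of logit tensors (class axis 1);
    each is softmaxed before the loss. ``u`` is the one-hot ground truth at
    the shared spatial size.
    """
    logit_list = outputs.all_outputs() if hasattr(outputs, "all_outputs") else list(outputs)
    if not logit_list:
        raise ValueError("deep supervision requires at least one output")
    u = as_tensor(u)
    losses = []
    for logits in logit_list:
        logits = as_tensor(logits)
        if logits.shape[-2:] != u.shape[-2:]:
            raise ValueError(
                f"output spatial size {logits.shape[-2:]} does not match "
                f"ground truth {u.shape[-2:]}")
        probs = logits.softmax(axis=1 if logits.ndim == 4 else 0)
        losses.append(as_tensor(compound_loss(u, probs, lambda1, lambda2)))
    if weights is None:
        weights = [1.0] * len(losses)
    value = stack_mean(losses, weights)
    grad_needed = any(isinstance(t, Tensor) and t.requires_grad for t in logit_list)
    return value if grad_needed else value.item()
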