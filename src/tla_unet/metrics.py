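"""Evaluation metrics: per-structure Dice (%) and exact Hausdorff distance.

DSC is ``100 * 2|P n T| / (|P| + |T|)`` on the binary masks of one label;
two empty masks score 100 by convention. The Hausdorff distance is the
exact (100th percentile) symmetric distance between *boundary* point sets,
where a boundary pixel is a mask pixel 4-adjacent to a non-mask pixel
(image borders count as outside). Distances are Euclidean and scaled by the
per-axis pixel spacing, so results are in physical units when spacing is
given. If either structure is empty the distance is undefined: it is
reported as NaN, excluded from case means and counted in the report.

``evaluate_case`` aggregates per-structure metrics over single masks or
aligned slice stacks and returns a tidy table (one row per structure plus a
``mean`` row); background (label 0) is never reported, and structures absent
from the ground truth are excluded from the means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion
from scipy.spatial.distance import cdist

__all__ = ["dsc", "hausdorff", "boundary_points", "evaluate_case"]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _binary(mask: np.ndarray, label: int) -> np.ndarray:
    return np.asarray(mask) == label


def dsc(pred: np.ndarray, truth: np.ndarray, label: int) -> float:
    """Dice similarity of one label as a percentage in [0, 100]."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p, t = _binary(pred, label), _binary(truth, label)
    denom = p.sum() + t.sum()
    if denom == 0:
        return 100.0
    return float(100.0 * 2.0 * np.logical_and(p, t).sum() / denom)


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Coordinates of mask pixels 4-adjacent to the outside."""
    mask = np.asarray(mask, dtype=bool)
    interior = binary_erosion(mask, structure=_CROSS, border_value=0)
    return np.argwhere(mask & ~interior)


def hausdorff(pred: np.ndarray, truth: np.ndarray, label: int,
              spacing: tuple[float, float] = (1.0, 1.0)) -> float:
    """Exact symmetric Hausdorff distance between label boundaries.

    Returns NaN when either mask is empty for ``label`` (flagged upstream,
    never silently zero).
    """
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p, t = _binary(pred, label), _binary(truth, label)
    if not p.any() or not t.any():
        return float("nan")
    bp = boundary_points(p) * np.asarray(spacing, dtype=float)
    bt = boundary_points(t) * np.asarray(spacing, dtype=float)
    d = cdist(bp, bt)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def evaluate_case(pred_stack: np.ndarray, truth_stack: np.ndarray,
                  labels, spacing: tuple[float, float] = (1.0, 1.0),
                  case_id: str = "case") -> pd.DataFrame:
    """Per-structure DSC/HD for one case (a mask or aligned stack of masks).

    Returns a DataFrame with columns ``case_id, structure, dsc_pct, hd`` and
    a final ``mean`` row (unweighted across evaluable structures and
    slices). Raises if no structure is evaluable.
    """
    pred = np.asarray(pred_stack)
    truth = np.asarray(truth_stack)
    if pred.shape != truth.shape:
        raise ValueError(f"stack shapes differ: {pred.shape} vs {truth.shape}")
    if pred.ndim == 2:
        pred, truth = pred[None], truth[None]

    rows = []
    for label in labels:
        if label == 0:
            raise ValueError("background (label 0) is not a reported structure")
        present = [s for s in range(truth.shape[0]) if (truth[s] == label).any()]
        if not present:
            continue   # absent from ground truth: excluded from means
        dscs = [dsc(pred[s], truth[s], label) for s in present]
        hds = [hausdorff(pred[s], truth[s], label, spacing) for s in present]
        finite_hds = [h for h in hds if np.isfinite(h)]
        rows.append({
            "case_id": case_id,
            "structure": int(label),
            "dsc_pct": float(np.mean(dscs)),
            "hd": float(np.mean(finite_hds)) if finite_hds else float("nan"),
            "n_slices": len(present),
            "n_hd_undefined": len(hds) - len(finite_hds),
        })
    if not rows:
        raise ValueError(f"no evaluable structure in case {case_id!r}")
    table = pd.DataFrame(rows)
    hd_vals = table["hd"].dropna()
    mean_row = {
        "case_id": case_id,
        "structure": "mean",
        "dsc_pct": float(table["dsc_pct"].mean()),
        "hd": float(hd_vals.mean()) if len(hd_vals) else float("nan"),
        "n_slices": int(table["n_slices"].max()),
        "n_hd_undefined": int(table["n_hd_undefined"].sum()),
    }
    return pd.concat([table, pd.DataFrame([mean_row])], ignore_index=True)
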