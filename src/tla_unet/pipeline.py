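"""Training and evaluation orchestration.

The public surface follows the model/results idiom: build a
:class:`SegmentationModel` from a :class:`~tla_unet.network.ModelConfig`,
call :meth:`~SegmentationModel.fit` with a dataset and a
:class:`TrainConfig`, and receive :class:`FitResults` carrying the loss
history, the best-validation parameters, per-epoch diagnostics and a
``summary()`` table. ``cross_validate`` repeats the fit over a patient-level
k-fold plan and reports mean +/- SD of the per-fold best scores.

Training follows the reference protocol: SGD with momentum 0.9, initial
learning rate 0.005, weight decay 1e-4, polynomial learning-rate decay
``lr = base_lr * (1 - iter/total)^0.9``, flip/rotation augmentation applied
with probability 0.5, the compound Dice + cross-entropy objective averaged
over the main, side and intermediate outputs, and retention of the
parameters that scored best on the validation split. Adam, AdamW and
AdaDelta are available as optimizer choices. Everything is seeded and
single-threaded, so a (seed, config, dataset) triple fully determines the
history and the checkpoint.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import rotate as nd_rotate

from . import metrics
from .autograd import Tensor
from .losses import deep_supervision_loss, one_hot
from .network import ModelConfig, TLAUNet, build_model
from .nn import make_optimizer
from .synthetic import LabeledSample
from .transformer import TransformerConfig

__all__ = [
    "TrainConfig",
    "kfold_split",
    "augment",
    "lr_at",
    "train",
    "cross_validate",
    "evaluate",
    "SegmentationModel",
    "FitResults",
    "smoke_benchmark",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "sgd"
    base_lr: float = 0.005
    momentum: float = 0.9
    weight_decay: float = 0.0001
    epochs: int = 50
    batch_size: int = 8
    augment_prob: float = 0.5
    small_angle: bool = False
    lambda1: float = 0.5
    lambda2: float = 0.5
    poly_power: float = 0.9
    val_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.base_lr <= 0:
            raise ValueError(f"base_lr must be > 0, got {self.base_lr}")
        if not 0.0 <= self.augment_prob <= 1.0:
            raise ValueError(f"augment_prob must be in [0, 1], got {self.augment_prob}")


# ---------------------------------------------------------------------------
# Protocol primitives


def kfold_split(ids, k: int, seed: int) -> list[list]:
    """Seeded, shuffled partition of sample identifiers into k folds.

    Splitting is by identifier (patient), never by image, so all images of
    one patient share a fold. Fold sizes differ by at most one.
    """
    ids = list(ids)
    if k > len(ids):
        raise ValueError(f"cannot make {k} folds from {len(ids)} ids")
    rng = np.random.default_rng(seed)
    order = list(np.asarray(ids, dtype=object)[rng.permutation(len(ids))])
    return [list(fold) for fold in np.array_split(np.asarray(order, dtype=object), k)]


def augment(sample: LabeledSample, prob: float, rng: np.random.Generator,
            small_angle: bool = False) -> LabeledSample:
    """Random flip and rotation, applied to image and mask identically.

    With probability ``prob`` a random flip (horizontal or vertical) is
    applied, and independently with probability ``prob`` a rotation by a
    multiple of 90 degrees (plus a small random angle when ``small_angle``,
    with nearest-neighbour mask resampling so labels stay intact).
    """
    if not 0.0 <= prob <= 1.0:
        raise ValueError(f"prob must be in [0, 1], got {prob}")
    image, mask = sample.image, sample.mask
    if rng.random() < prob:
        axis = int(rng.integers(2))
        image, mask = np.flip(image, axis), np.flip(mask, axis)
    if rng.random() < prob:
        quarter = int(rng.integers(1, 4))
        image, mask = np.rot90(image, quarter), np.rot90(mask, quarter)
        if small_angle:
            angle = float(rng.uniform(-15.0, 15.0))
            image = nd_rotate(image.astype(np.float64), angle, reshape=False,
                              order=1, mode="nearest")
            image = np.clip(np.round(image), 0, 255).astype(np.uint8)
            mask = nd_rotate(mask, angle, reshape=False, order=0, mode="nearest")
    return LabeledSample(np.ascontiguousarray(image),
                         np.ascontiguousarray(mask),
                         sample.sample_id, sample.spacing)


def lr_at(iteration: int, total_iterations: int, cfg: TrainConfig) -> float:
    """Polynomial decay: base_lr * (1 - iter/total)^0.9."""
    if total_iterations <= 0:
        raise ValueError("total_iterations must be positive")
    if not 0 <= iteration <= total_iterations:
        raise ValueError(f"iteration {iteration} outside [0, {total_iterations}]")
    frac = 1.0 - iteration / total_iterations
    return cfg.base_lr * frac ** cfg.poly_power


# ---------------------------------------------------------------------------
# Fitting


def _net_input(sample: LabeledSample) -> np.ndarray:
    """Per-image z-score normalisation, the network's input convention."""
    x = sample.image_float()
    return (x - x.mean()) / (x.std() + 1e-8)


def _batch_arrays(samples: list[LabeledSample], n_classes: int):
    images = np.stack([_net_input(s)[None] for s in samples]).astype(np.float32)
    masks = np.stack([s.mask for s in samples])
    return images, one_hot(masks, n_classes).astype(np.float32)


def _predict_batched(model: TLAUNet, samples: list[LabeledSample],
                     batch_size: int = 8) -> np.ndarray:
    model.eval()
    preds = []
    for i in range(0, len(samples), batch_size):
        chunk = samples[i:i + batch_size]
        images = np.stack([_net_input(s)[None] for s in chunk]).astype(np.float32)
        preds.append(model(images).predictions())
    return np.concatenate(preds)


def _mean_foreground_dsc(model: TLAUNet, samples: list[LabeledSample]) -> float:
    """Mean over samples of the mean DSC across foreground labels present."""
    preds = _predict_batched(model, samples)
    scores = []
    for pred, s in zip(preds, samples):
        labels = [l for l in range(1, model.cfg.n_classes) if (s.mask == l).any()]
        if labels:
            scores.append(np.mean([metrics.dsc(pred, s.mask, l) for l in labels]))
    return float(np.mean(scores)) if scores else float("nan")


@dataclass
class FitResults:
    """Outcome of one training run: history, best parameters, diagnostics."""

    model: TLAUNet
    train_cfg: TrainConfig
    history: pd.DataFrame          # epoch, train_loss, lr, val_dsc
    best_state: dict
    best_epoch: int
    best_val_dsc: float
    n_train: int
    n_val: int

    def restore_best(self) -> TLAUNet:
        self.model.load_state_dict(self.best_state)
        return self.model

    def evaluate(self, dataset: list[LabeledSample]) -> pd.DataFrame:
        return evaluate(self.restore_best(), dataset)

    def save(self, path) -> None:
        save_checkpoint(self, path)

    def summary(self) -> str:
        cfg = self.model.cfg
        lines = [
            "Segmentation model fit",
            "=" * 58,
            f"classes: {cfg.n_classes}   input: {cfg.input_size}px   "
            f"depth: {cfg.depth}   base width: {cfg.base_width}",
            f"transformer: hidden {cfg.transformer.hidden_size}, "
            f"{cfg.transformer.n_layers} layers, {cfg.transformer.n_heads} heads, "
            f"{cfg.n_tokens} tokens",
            f"switches: unetpp={cfg.use_unetpp} side={cfg.use_side_outputs} "
            f"tla={cfg.use_tla} se={cfg.use_se}",
            f"parameters: {self.model.n_parameters():,}",
            f"optimizer: {self.train_cfg.optimizer} (lr {self.train_cfg.base_lr}, "
            f"momentum {self.train_cfg.momentum}, wd {self.train_cfg.weight_decay})",
            f"samples: {self.n_train} train / {self.n_val} validation",
            "-" * 58,
            f"epochs run: {len(self.history)}",
            f"final train loss: {self.history['train_loss'].iloc[-1]:.4f}",
            f"best val DSC: {self.best_val_dsc:.2f}% (epoch {self.best_epoch})",
            "=" * 58,
        ]
        return "\n".join(lines)


def train(model_cfg: ModelConfig | TLAUNet, train_cfg: TrainConfig,
          dataset: list[LabeledSample],
          val_dataset: list[LabeledSample] | None = None) -> FitResults:
    """Fit the network on ``dataset``; see the module docstring for protocol."""
    if not dataset:
        raise ValueError("dataset is empty")
    model = model_cfg if isinstance(model_cfg, TLAUNet) else build_model(model_cfg)
    n_classes = model.cfg.n_classes

    rng = np.random.default_rng(train_cfg.seed)
    if val_dataset is None:
        ids = [s.sample_id for s in dataset]
        n_val = max(1, int(round(train_cfg.val_fraction * len(ids))))
        val_ids = set(np.asarray(ids, dtype=object)[
            rng.permutation(len(ids))[:n_val]])
        val_dataset = [s for s in dataset if s.sample_id in val_ids]
        train_set = [s for s in dataset if s.sample_id not in val_ids]
    else:
        train_set = list(dataset)
    if not train_set:
        raise ValueError("no training samples left after validation split")

    optimizer = make_optimizer(train_cfg.optimizer, model.parameters(), train_cfg)
    bs = train_cfg.batch_size
    n_batches = (len(train_set) + bs - 1) // bs
    total_iters = train_cfg.epochs * n_batches

    records = []
    best_state, best_epoch, best_val = model.state_dict(), 0, -np.inf
    it = 0
    for epoch in range(1, train_cfg.epochs + 1):
        model.train()
        order = rng.permutation(len(train_set))
        epoch_loss, seen = 0.0, 0
        for b in range(n_batches):
            batch_idx = order[b * bs:(b + 1) * bs]
            batch = [augment(train_set[i], train_cfg.augment_prob, rng,
                             train_cfg.small_angle) for i in batch_idx]
            images, targets = _batch_arrays(batch, n_classes)
            outputs = model(images)
            loss = deep_supervision_loss(
                outputs, Tensor(targets), train_cfg.lambda1, train_cfg.lambda2,
                model.cfg.deep_supervision_weights)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch {b} (lr {optimizer.lr:.3g})")
            optimizer.zero_grad()
            loss.backward()
            optimizer.lr = lr_at(it, total_iters, train_cfg)
            optimizer.step()
            it += 1
            epoch_loss += loss.item() * len(batch)
            seen += len(batch)
        val_dsc = _mean_foreground_dsc(model, val_dataset) if val_dataset else float("nan")
        records.append({"epoch": epoch, "train_loss": epoch_loss / seen,
                        "lr": optimizer.lr, "val_dsc": val_dsc})
        if val_dataset and val_dsc > best_val:
            best_state, best_epoch, best_val = model.state_dict(), epoch, val_dsc
    if not val_dataset:
        best_state, best_epoch = model.state_dict(), train_cfg.epochs

    return FitResults(model=model, train_cfg=train_cfg,
                      history=pd.DataFrame(records), best_state=best_state,
                      best_epoch=best_epoch, best_val_dsc=float(best_val),
                      n_train=len(train_set), n_val=len(val_dataset))


def evaluate(model: TLAUNet, dataset: list[LabeledSample]) -> pd.DataFrame:
    """Per-case metric table for a fitted model (argmax predictions)."""
    preds = _predict_batched(model, dataset)
    tables = []
    labels = list(range(1, model.cfg.n_classes))
    for pred, s in zip(preds, dataset):
        tables.append(metrics.evaluate_case(pred, s.mask, labels,
                                            spacing=s.spacing,
                                            case_id=s.sample_id))
    table = pd.concat(tables, ignore_index=True)
    means = table[table["structure"] == "mean"]
    summary = pd.DataFrame([{
        "case_id": "ALL", "structure": "mean",
        "dsc_pct": float(means["dsc_pct"].mean()),
        "hd": float(means["hd"].dropna().mean()) if means["hd"].notna().any() else float("nan"),
        "n_slices": int(means["n_slices"].max()),
        "n_hd_undefined": int(means["n_hd_undefined"].sum()),
    }])
    return pd.concat([table, summary], ignore_index=True)


def cross_validate(model_cfg: ModelConfig, train_cfg: TrainConfig,
                   dataset: list[LabeledSample], k: int) -> pd.DataFrame:
    """k-fold cross-validation; each fold is the validation set once.

    Returns one row per fold (best val DSC/HD) plus mean and sample-SD rows.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    by_id = {s.sample_id: s for s in dataset}
    folds = kfold_split(sorted(by_id), k, train_cfg.seed)
    rows = []
    for fold_idx, fold_ids in enumerate(folds):
        held = set(fold_ids)
        train_set = [s for s in dataset if s.sample_id not in held]
        val_set = [s for s in dataset if s.sample_id in held]
        fold_model_cfg = dataclasses.replace(model_cfg,
                                             seed=model_cfg.seed + fold_idx)
        try:
            result = train(fold_model_cfg, train_cfg, train_set, val_set)
            report = result.evaluate(val_set)
        except Exception as exc:
            raise RuntimeError(f"fold {fold_idx} failed: {exc}") from exc
        overall = report[report["case_id"] == "ALL"].iloc[0]
        rows.append({"fold": fold_idx, "n_val": len(val_set),
                     "dsc_pct": float(overall["dsc_pct"]),
                     "hd": float(overall["hd"])})
    table = pd.DataFrame(rows)
    stats = pd.DataFrame([
        {"fold": "mean", "n_val": table["n_val"].sum(),
         "dsc_pct": table["dsc_pct"].mean(), "hd": table["hd"].mean()},
        {"fold": "sd", "n_val": table["n_val"].sum(),
         "dsc_pct": table["dsc_pct"].std(ddof=1), "hd": table["hd"].std(ddof=1)},
    ])
    return pd.concat([table, stats], ignore_index=True)


# ---------------------------------------------------------------------------
# Model/Results facade and checkpointing


class SegmentationModel:
    """User-facing model object; ``fit`` returns :class:`FitResults`."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.network = build_model(config)

    @classmethod
    def from_yaml(cls, path) -> "SegmentationModel":
        with open(path) as fh:
            return cls(model_config_from_dict(yaml.safe_load(fh)))

    def fit(self, dataset: list[LabeledSample], train_cfg: TrainConfig,
            val_dataset: list[LabeledSample] | None = None) -> FitResults:
        return train(self.network, train_cfg, dataset, val_dataset)

    def cross_validate(self, dataset, train_cfg: TrainConfig, k: int) -> pd.DataFrame:
        return cross_validate(self.config, train_cfg, dataset, k)

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Segment one grayscale image ([0, 1] or uint8) into a label mask."""
        x = np.asarray(image, dtype=np.float64)
        if x.max() > 1.5:      # 8-bit input
            x = x / 255.0
        x = (x - x.mean()) / (x.std() + 1e-8)
        self.network.eval()
        return self.network(x[None, None].astype(np.float32)).predictions()[0]


def smoke_benchmark(seed: int = 0):
    """The package's standard desk-scale learning benchmark.

    Returns ``(phantom_spec, model_config, train_config)`` for: 64 phantoms
    of 64x64 pixels with 3 structures, the desk-scale network at width 24,
    and 10 epochs of single-sample SGD at the reference hyperparameters
    with a 56/8 train/validation split. ``seed`` drives both the dataset
    and the training run.
    """
    from .network import desk_scale_config
    from .synthetic import PhantomSpec
    spec = PhantomSpec(n_samples=64, image_size=64, n_structures=3, seed=seed)
    model_cfg = desk_scale_config(base_width=24)
    train_cfg = TrainConfig(epochs=10, batch_size=1, val_fraction=0.125,
                            seed=seed)
    return spec, model_cfg, train_cfg


def model_config_to_dict(cfg: ModelConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["deep_supervision_weights"] = (
        list(cfg.deep_supervision_weights)
        if cfg.deep_supervision_weights is not None else None)
    return d


def model_config_from_dict(d: dict) -> ModelConfig:
    d = dict(d)
    tf = d.pop("transformer", {})
    weights = d.pop("deep_supervision_weights", None)
    return ModelConfig(transformer=TransformerConfig(**tf),
                       deep_supervision_weights=tuple(weights) if weights else None,
                       **d)


def save_checkpoint(results: FitResults, path) -> None:
    """Single-file checkpoint: YAML configs + parameters + training state."""
    path = Path(path)
    payload = {f"param/{k}": v for k, v in results.best_state.items()}
    payload["meta/model_yaml"] = np.frombuffer(
        yaml.safe_dump(model_config_to_dict(results.model.cfg)).encode(), dtype=np.uint8)
    payload["meta/train_yaml"] = np.frombuffer(
        yaml.safe_dump(dataclasses.asdict(results.train_cfg)).encode(), dtype=np.uint8)
    payload["meta/best_epoch"] = np.array(results.best_epoch)
    payload["meta/best_val_dsc"] = np.array(results.best_val_dsc)
    payload["meta/history_csv"] = np.frombuffer(
        results.history.to_csv(index=False).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_checkpoint(path) -> tuple[TLAUNet, TrainConfig, pd.DataFrame]:
    with np.load(path) as data:
        model_cfg = model_config_from_dict(
            yaml.safe_load(bytes(data["meta/model_yaml"]).decode()))
        train_cfg = TrainConfig(**yaml.safe_load(
            bytes(data["meta/train_yaml"]).decode()))
        history = pd.read_csv(io.StringIO(bytes(data["meta/history_csv"]).decode()))
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
    model = build_model(model_cfg)
    model.load_state_dict(state)
    model.eval()
    return model, train_cfg, history
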