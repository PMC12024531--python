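"""Training recipe, patient-grouped splitting, 5-fold cross-validation with
median-model selection, and the regularization ablation runner.

The canonical recipe follows the study protocol: Adam at an initial learning
rate of 5e-5 halved every 250 epochs, batch size 32, cross-entropy loss,
weight decay 1e-5, dropout 0.8, 2000 epochs at 360-px input.  Desk presets
(:meth:`TrainConfig.desk`) shrink the input side and epoch budget so the full
pipeline runs in minutes on one CPU; they are what the test-suite uses.

All splits and folds are patient-grouped: no patient ever contributes images
to both sides of a split, which is the leakage-safe reading of the study's
patient-level dataset description.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .archnet import ArchitectureSpec, build_model, spec_from_config, spec_to_config
from .augment import NormalizationStats, compute_normalization, crop_centered
from .errors import ConfigError, DataError
from .phantom import GIST, PhantomDataset

__all__ = [
    "TrainConfig",
    "FoldResult",
    "CVReport",
    "AblationResult",
    "ArrayDataset",
    "TrainedModel",
    "lr_at",
    "split_train_val",
    "kfold",
    "median_fold",
    "train",
    "train_network",
    "crossval",
    "run_ablation",
    "arrays_from_phantoms",
    "save_run",
]

LABEL_TO_INDEX = {"leiomyoma": 0, "GIST": 1}  # GIST is the positive class


@dataclass(frozen=True)
class TrainConfig:
    initial_lr: float = 5e-5
    batch_size: int = 32
    epochs: int = 2000
    lr_half_every: int = 250
    weight_decay: float = 1e-5
    dropout_rate: float = 0.8
    loss: str = "cross_entropy"
    optimizer: str = "adam"
    seed: int = 0
    input_side: int = 360
    val_ratio: float = 0.3  # used when train() has to split internally
    #: random quarter-turn augmentation during training (exact rot90 about the
    #: probe-centered crop, no resampling) — the cheap in-loop counterpart of
    #: the offline 22.5-degree augmentation pipeline
    quarter_turn_augment: bool = False

    def __post_init__(self):
        if self.initial_lr <= 0 or self.batch_size < 1 or self.lr_half_every < 1:
            raise ConfigError("initial_lr > 0, batch_size >= 1, lr_half_every >= 1 required")
        if self.loss != "cross_entropy" or self.optimizer != "adam":
            raise ConfigError("only cross_entropy loss with adam is supported")

    @classmethod
    def desk(cls, input_side: int = 96, epochs: int = 60, seed: int = 0,
             **overrides) -> "TrainConfig":
        """Desk-scale preset: larger learning rate, short halving period and a
        small input so a full run takes minutes on one CPU."""
        base = cls(initial_lr=5e-4, batch_size=32, epochs=epochs, lr_half_every=15,
                   weight_decay=1e-5, dropout_rate=0.5, seed=seed,
                   input_side=input_side, quarter_turn_augment=True)
        return replace(base, **overrides)

    @classmethod
    def resnet_probe(cls, epochs: int = 400, weight_decay: float = 1e-5,
                     seed: int = 0, input_side: int = 360,
                     **overrides) -> "TrainConfig":
        """The ResNet-18 comparison recipe: lr 5e-4 halved every 20 epochs;
        weight decay 0.05 (suppressed) or 1e-5 (overfitting probe).  Tests use
        far smaller epoch counts and input sides."""
        base = cls(initial_lr=5e-4, batch_size=16, epochs=epochs,
                   lr_half_every=20, weight_decay=weight_decay,
                   dropout_rate=0.0, seed=seed, input_side=input_side)
        return replace(base, **overrides)


@dataclass
class FoldResult:
    fold_index: int
    train_loss_curve: list[float]
    val_loss_curve: list[float]
    val_accuracy_curve: list[float]
    train_accuracy_curve: list[float]
    final_val_accuracy: float
    final_val_loss: float
    final_train_accuracy: float
    model: "TrainedModel"
    checkpoint_path: str | None = None

    @property
    def train_val_gap(self) -> float:
        """Final (eval-mode) train accuracy minus final validation accuracy."""
        return self.final_train_accuracy - self.final_val_accuracy


@dataclass
class CVReport:
    fold_results: list[FoldResult]
    mean_accuracy: float
    selected_fold: int

    @property
    def selected(self) -> FoldResult:
        return self.fold_results[self.selected_fold]


@dataclass
class AblationResult:
    kind: str
    base: FoldResult
    variant: FoldResult
    base_gap: float
    variant_gap: float


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class ArrayDataset:
    """Images as (N, 1, S, S) float32 in [0, 1] plus per-image metadata."""

    x: np.ndarray
    y: np.ndarray
    patient_ids: np.ndarray
    lesion_sizes: np.ndarray | None = None
    masks: np.ndarray | None = None

    def __post_init__(self):
        if self.x.ndim != 4 or self.x.shape[1] != 1:
            raise DataError(f"expected (N, 1, S, S) images, got {self.x.shape}")
        if len(self.y) != len(self.x):
            raise DataError("labels and images disagree in length")

    def __len__(self) -> int:
        return len(self.x)

    def subset(self, idx) -> "ArrayDataset":
        idx = np.asarray(idx)
        return ArrayDataset(
            x=self.x[idx],
            y=self.y[idx],
            patient_ids=self.patient_ids[idx],
            lesion_sizes=None if self.lesion_sizes is None else self.lesion_sizes[idx],
            masks=None if self.masks is None else self.masks[idx],
        )

    def by_patients(self, ids) -> "ArrayDataset":
        wanted = set(ids)
        return self.subset([i for i, p in enumerate(self.patient_ids) if p in wanted])


def arrays_from_phantoms(dataset: PhantomDataset, input_side: int) -> ArrayDataset:
    """Center-crop every phantom frame (and its lesion mask) to the model
    input side."""
    xs, ys, pids, sizes, masks = [], [], [], [], []
    for rec in dataset.records:
        crop = crop_centered(rec.frame, input_side)
        mask_frame = replace(rec.frame, pixels=rec.lesion_mask.astype(np.float32))
        masks.append(crop_centered(mask_frame, input_side) > 0.5)
        xs.append(crop.astype(np.float32))
        ys.append(LABEL_TO_INDEX[rec.frame.label])
        pids.append(rec.frame.patient_id)
        sizes.append(rec.frame.lesion_size_mm)
    return ArrayDataset(
        x=np.stack(xs)[:, None, :, :],
        y=np.asarray(ys, dtype=np.int64),
        patient_ids=np.asarray(pids, dtype=object),
        lesion_sizes=np.asarray(sizes, dtype=np.float64),
        masks=np.stack(masks),
    )


# ---------------------------------------------------------------------------
# schedules and splits
# ---------------------------------------------------------------------------

def lr_at(epoch: int, config: TrainConfig) -> float:
    """initial_lr * 0.5 ** floor(epoch / lr_half_every)."""
    if epoch < 0:
        raise ConfigError(f"epoch must be >= 0, got {epoch}")
    return config.initial_lr * 0.5 ** (epoch // config.lr_half_every)


def split_train_val(patient_ids, ratio: float = 0.7, seed: int = 0):
    """Patient-level 7:3-style split: round(ratio * n) patients to training."""
    ids = list(dict.fromkeys(patient_ids))  # unique, order-preserving
    if len(ids) < 2:
        raise ConfigError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(ratio * len(ids)))
    train = [ids[i] for i in sorted(perm[:n_train])]
    val = [ids[i] for i in sorted(perm[n_train:])]
    return train, val


def kfold(patient_ids, k: int = 5, seed: int = 0) -> list[list]:
    """Patient-grouped folds: pairwise disjoint, exhaustive, sizes differing
    by at most one."""
    ids = list(dict.fromkeys(patient_ids))
    if k < 2:
        raise ConfigError("cross-validation needs k >= 2")
    if len(ids) < k:
        raise ConfigError(f"cannot make {k} folds from {len(ids)} patients")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return [[ids[i] for i in chunk] for chunk in np.array_split(perm, k)]


# ---------------------------------------------------------------------------
# the trained model wrapper
# ---------------------------------------------------------------------------

class TrainedModel:
    """A trained network plus the preprocessing it was trained with."""

    def __init__(self, spec: ArchitectureSpec, net: nn.Sequential,
                 stats: NormalizationStats, trained: bool = False):
        self.spec = spec
        self.net = net
        self.stats = stats
        self.trained = trained  # False flags saliency on random weights

    def predict_scores(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """P(GIST) per image; ``x`` is (N, 1, S, S) raw intensities in [0, 1]."""
        out = []
        for i in range(0, len(x), batch_size):
            xb = self.stats.apply(x[i : i + batch_size]).astype(np.float32)
            logits = self.net.forward(xb, train=False)
            out.append(nn.softmax(logits)[:, LABEL_TO_INDEX[GIST]])
        return np.concatenate(out)

    def predict_labels(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return (self.predict_scores(x, batch_size) >= 0.5).astype(np.int64)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        state = self.net.state_dict()
        state["__mean"] = np.float64(self.stats.mean)
        state["__std"] = np.float64(self.stats.std)
        state["__spec"] = np.frombuffer(
            json.dumps(spec_to_config(self.spec)).encode(), dtype=np.uint8
        )
        np.savez(path, **state)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        data = dict(np.load(Path(path), allow_pickle=False))
        cfg = json.loads(bytes(data.pop("__spec").tobytes()).decode())
        stats = NormalizationStats(float(data.pop("__mean")), float(data.pop("__std")))
        spec = spec_from_config(cfg)
        net = build_model(spec)
        net.load_state_dict(data)
        return cls(spec, net, stats, trained=True)


def _evaluate(net: nn.Sequential, x: np.ndarray, y: np.ndarray,
              batch_size: int = 64) -> tuple[float, float]:
    """Eval-mode mean loss and accuracy."""
    losses, correct = [], 0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        logits = net.forward(xb, train=False)
        loss, _ = nn.cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _resolve_split(dataset: ArrayDataset, config: TrainConfig,
                   val: ArrayDataset | None):
    if len(dataset) == 0:
        raise DataError("empty training dataset")
    if val is not None:
        return dataset, val
    tr_ids, va_ids = split_train_val(
        dataset.patient_ids, 1.0 - config.val_ratio, config.seed
    )
    return dataset.by_patients(tr_ids), dataset.by_patients(va_ids)


def train(
    spec: ArchitectureSpec,
    dataset: ArrayDataset,
    config: TrainConfig,
    val: ArrayDataset | None = None,
    fold_index: int = 0,
) -> FoldResult:
    """Train one model; returns per-epoch curves and the trained model.

    If ``val`` is omitted the dataset is split patient-wise at
    ``1 - config.val_ratio``.  Normalization statistics are computed on the
    training portion only and applied to both sides.
    """
    if dataset.x.shape[-1] != spec.input_side:
        raise DataError(
            f"images of side {dataset.x.shape[-1]} do not match spec input_side "
            f"{spec.input_side}"
        )
    spec = replace(spec, dropout_rate=config.dropout_rate)
    net = build_model(spec, seed=config.seed)
    return train_network(net, dataset, config, val=val, fold_index=fold_index,
                         spec=spec)


def train_network(
    net: nn.Sequential,
    dataset: ArrayDataset,
    config: TrainConfig,
    val: ArrayDataset | None = None,
    fold_index: int = 0,
    spec: ArchitectureSpec | None = None,
) -> FoldResult:
    """The training loop on an already-built network (used directly for the
    ResNet-18 baseline comparisons)."""
    train_set, val_set = _resolve_split(dataset, config, val)
    stats = compute_normalization([train_set.x])
    xtr = stats.apply(train_set.x).astype(np.float32)
    xva = stats.apply(val_set.x).astype(np.float32)
    ytr, yva = train_set.y, val_set.y

    net.set_dropout_rng(np.random.default_rng(config.seed + 1))
    opt = nn.Adam(net.parameters(), lr=config.initial_lr,
                  weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 2)

    curves = {"train_loss": [], "val_loss": [], "val_acc": [], "train_acc": []}
    for epoch in range(config.epochs):
        opt.lr = lr_at(epoch, config)
        order = rng.permutation(len(xtr))
        epoch_loss = 0.0
        epoch_correct = 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            xb = xtr[idx]
            if config.quarter_turn_augment:
                xb = xb.copy()
                turns = rng.integers(0, 4, size=len(idx))
                for j, k in enumerate(turns):
                    if k:
                        xb[j, 0] = np.rot90(xb[j, 0], k)
            logits = net.forward(xb, train=True)
            loss, dlogits = nn.cross_entropy(logits, ytr[idx])
            if not np.isfinite(loss):
                raise ArithmeticError(f"training diverged (non-finite loss) at epoch {epoch}")
            net.zero_grad()
            net.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
            epoch_correct += int((logits.argmax(axis=1) == ytr[idx]).sum())
        val_loss, val_acc = _evaluate(net, xva, yva)
        curves["train_loss"].append(epoch_loss / len(xtr))
        curves["val_loss"].append(val_loss)
        curves["val_acc"].append(val_acc)
        # in-training estimate (dropout active); a clean eval-mode pass over
        # the training set happens once at the end
        curves["train_acc"].append(epoch_correct / len(xtr))

    _, final_train_acc = _evaluate(net, xtr, ytr)
    curves["train_acc"][-1] = final_train_acc
    model = TrainedModel(spec or ArchitectureSpec(units=(), family_code="custom"),
                         net, stats, trained=True)
    return FoldResult(
        fold_index=fold_index,
        train_loss_curve=curves["train_loss"],
        val_loss_curve=curves["val_loss"],
        val_accuracy_curve=curves["val_acc"],
        train_accuracy_curve=curves["train_acc"],
        final_val_accuracy=curves["val_acc"][-1],
        final_val_loss=curves["val_loss"][-1],
        final_train_accuracy=curves["train_acc"][-1],
        model=model,
    )


def crossval(
    spec: ArchitectureSpec,
    dataset: ArrayDataset,
    config: TrainConfig,
    k: int = 5,
) -> CVReport:
    """Patient-grouped k-fold cross-validation with median-model selection.

    The selected fold is the one whose final validation accuracy equals the
    median of the fold accuracies (for even k, the lower of the two middle
    values); ties are broken by the lowest final validation loss.
    """
    folds = kfold(dataset.patient_ids, k=k, seed=config.seed)
    results: list[FoldResult] = []
    for i, fold_ids in enumerate(folds):
        val_set = dataset.by_patients(fold_ids)
        train_ids = [p for f in folds for p in f if f is not fold_ids]
        train_set = dataset.by_patients(train_ids)
        results.append(train(spec, train_set, config, val=val_set, fold_index=i))

    accs = [r.final_val_accuracy for r in results]
    losses = [r.final_val_loss for r in results]
    return CVReport(
        fold_results=results,
        mean_accuracy=float(np.mean(accs)),
        selected_fold=median_fold(accs, losses),
    )


def median_fold(accuracies, losses=None) -> int:
    """Index of the fold with median accuracy.

    For even k the lower of the two middle values is taken; ties on the
    median accuracy are broken by the lowest final validation loss.
    """
    accs = np.asarray(accuracies, dtype=float)
    k = len(accs)
    if k == 0:
        raise ConfigError("no folds")
    median_value = np.sort(accs)[(k - 1) // 2]
    candidates = np.flatnonzero(accs == median_value)
    if losses is None or len(candidates) == 1:
        return int(candidates[0])
    losses = np.asarray(losses, dtype=float)
    return int(candidates[np.argmin(losses[candidates])])


ABLATION_KINDS = ("dropout_rate", "batchnorm", "weight_decay")


def run_ablation(
    kind: str,
    base_config: TrainConfig,
    variant_value,
    spec: ArchitectureSpec,
    dataset: ArrayDataset,
    val: ArrayDataset | None = None,
) -> AblationResult:
    """Train base and variant arms on identical data and seeds.

    ``dropout_rate``: variant_value replaces the dropout rate;
    ``batchnorm``: variant_value False strips batch-norm (dropout and weight
    decay retained); ``weight_decay``: variant_value replaces the decay.
    """
    if kind not in ABLATION_KINDS:
        raise ConfigError(f"unknown ablation kind {kind!r}; one of {ABLATION_KINDS}")
    base_spec, var_spec = spec, spec
    var_config = base_config
    if kind == "dropout_rate":
        var_config = replace(base_config, dropout_rate=float(variant_value))
    elif kind == "weight_decay":
        var_config = replace(base_config, weight_decay=float(variant_value))
    elif kind == "batchnorm":
        if bool(variant_value):
            raise ConfigError("batchnorm ablation variant must disable batch-norm")
        var_spec = replace(
            spec, units=tuple(replace(u, has_batchnorm=False) for u in spec.units)
        )
    base = train(base_spec, dataset, base_config, val=val, fold_index=0)
    variant = train(var_spec, dataset, var_config, val=val, fold_index=1)
    return AblationResult(
        kind=kind,
        base=base,
        variant=variant,
        base_gap=base.train_val_gap,
        variant_gap=variant.train_val_gap,
    )


# ---------------------------------------------------------------------------
# run-directory logging
# ---------------------------------------------------------------------------

def save_run(run_dir: str | Path, config: TrainConfig, result: FoldResult,
             run_id: str = "run") -> Path:
    """Write the standard run layout: config snapshot, per-epoch CSV log,
    checkpoint, and a final JSON report."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.json").write_text(
        json.dumps({"run_id": run_id, **config.__dict__,
                    "architecture": spec_to_config(result.model.spec)}, indent=2)
    )
    log = pd.DataFrame(
        {
            "epoch": np.arange(len(result.train_loss_curve)),
            "lr": [lr_at(e, config) for e in range(len(result.train_loss_curve))],
            "train_loss": result.train_loss_curve,
            "val_loss": result.val_loss_curve,
            "val_acc": result.val_accuracy_curve,
            "train_acc": result.train_accuracy_curve,
        }
    )
    log.to_csv(run_dir / "log.csv", index=False)
    ckpt = run_dir / "checkpoint.npz"
    result.model.save(ckpt)
    result.checkpoint_path = str(ckpt)
    report = {
        "run_id": run_id,
        "fold_index": result.fold_index,
        "final_val_accuracy": result.final_val_accuracy,
        "final_val_loss": result.final_val_loss,
        "final_train_accuracy": result.final_train_accuracy,
        "train_val_gap": result.train_val_gap,
        "checkpoint": str(ckpt),
    }
    (run_dir / "report.json").write_text(json.dumps(report, indent=2))
    return run_dir
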