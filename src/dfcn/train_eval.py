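"""Experimental protocol harness.

Dataset splitting, SGD training with periodic checkpointing, validation Dice
curves, optimal-checkpoint selection, and test-set evaluation.  Everything is
seed-deterministic: the same seeds reproduce the same splits, loss
trajectories, curves, and selected checkpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .arch import ArchitectureSpec
from .metrics import DiceReport, aggregate_reports, dice_report
from .network import (NetworkInstance, forward, forward_backward, init_network,
                      predict_labels)

__all__ = [
    "TrainingConfig",
    "SplitSpec",
    "CheckpointRecord",
    "DiceCurve",
    "SliceDataset",
    "split_dataset",
    "train",
    "validate_checkpoints",
    "select_optimal",
    "evaluate_test",
    "evaluate_case",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of one training run.

    Defaults are this artifact's: step decay (x0.1 at 50% and 75% of the
    iteration budget), SGD with momentum and weight decay, per-pixel softmax
    cross-entropy with optional per-class weights.
    """

    learning_strategy: str = "step"  # fixed | step
    initial_lr: float = 1e-3
    batch_size: int = 4
    momentum: float = 0.9
    weight_decay: float = 5e-4
    max_iterations: int = 500_000
    checkpoint_interval: int = 5_000
    seed: int = 0
    loss: str = "cross_entropy"
    class_weights: tuple | None = None
    augment_flips: bool = False

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.max_iterations < 1 or self.checkpoint_interval < 1:
            raise ValueError("batch_size, max_iterations, checkpoint_interval must be >= 1")
        if self.checkpoint_interval > self.max_iterations:
            raise ValueError("checkpoint_interval must not exceed max_iterations")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must be in [0, 1)")
        if self.weight_decay < 0 or self.initial_lr <= 0:
            raise ValueError("initial_lr must be > 0 and weight_decay >= 0")

    def lr_at(self, iteration: int) -> float:
        if self.learning_strategy == "fixed":
            return self.initial_lr
        lr = self.initial_lr
        if iteration >= 0.75 * self.max_iterations:
            return lr * 0.01
        if iteration >= 0.5 * self.max_iterations:
            return lr * 0.1
        return lr


@dataclass(frozen=True)
class SplitSpec:
    train_cases: tuple
    val_cases: tuple
    test_cases: tuple
    seed: int

    def __post_init__(self) -> None:
        sets = [set(self.train_cases), set(self.val_cases), set(self.test_cases)]
        n = sum(len(s) for s in sets)
        if len(set().union(*sets)) != n:
            raise ValueError("split case lists must be pairwise disjoint")


@dataclass
class CheckpointRecord:
    iteration: int
    params: dict[str, np.ndarray]
    arch: ArchitectureSpec
    validation_global_dice: float | None = None


@dataclass
class DiceCurve:
    """Ordered (iteration, global Dice) points for one model."""

    points: list[tuple[int, float]]
    variant: str = ""

    def __post_init__(self) -> None:
        its = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(its, its[1:])):
            raise ValueError("curve iterations must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)


class SliceDataset:
    """Cases of (HU volume, mask volume) pairs, addressable per case or as a
    flat slice list for sampling."""

    def __init__(self, cases: list[tuple[str, np.ndarray, np.ndarray]]):
        if not cases:
            raise ValueError("dataset must contain at least one case")
        for cid, img, msk in cases:
            if img.shape != msk.shape:
                raise ValueError(f"case {cid}: image shape {img.shape} != mask {msk.shape}")
        self.cases = cases
        self._flat = [(img[s], msk[s]) for _, img, msk in cases
                      for s in range(img.shape[0])]

    @classmethod
    def from_phantom_cases(cls, cases) -> "SliceDataset":
        return cls([(c.case_id, c.images, c.masks) for c in cases])

    @classmethod
    def from_manifest(cls, manifest, root) -> "SliceDataset":
        from pathlib import Path

        from .io_utils import read_mask, read_volume

        root = Path(root)
        rows = []
        for _, row in manifest.iterrows():
            img, _ = read_volume(root / row["image"])
            msk, _ = read_mask(root / row["mask"])
            rows.append((str(row["case_id"]), img, msk))
        return cls(rows)

    def subset(self, case_ids) -> "SliceDataset":
        wanted = set(case_ids)
        return SliceDataset([c for c in self.cases if c[0] in wanted])

    @property
    def case_ids(self) -> list[str]:
        return [c[0] for c in self.cases]

    @property
    def n_slices(self) -> int:
        return len(self._flat)

    def slice(self, i: int):
        return self._flat[i]


def split_dataset(case_ids, sizes, seed: int) -> SplitSpec:
    """Uniformly random disjoint train/val/test assignment."""
    case_ids = list(case_ids)
    n_train, n_val, n_test = sizes
    if n_train + n_val + n_test != len(case_ids):
        raise ValueError(f"split sizes {sizes} must sum to the number of cases "
                         f"({len(case_ids)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(case_ids))
    ordered = [case_ids[i] for i in perm]
    return SplitSpec(
        train_cases=tuple(ordered[:n_train]),
        val_cases=tuple(ordered[n_train:n_train + n_val]),
        test_cases=tuple(ordered[n_train + n_val:]),
        seed=seed,
    )


def train(net: NetworkInstance, train_set: SliceDataset, cfg: TrainingConfig,
          log_fn=None) -> list[CheckpointRecord]:
    """SGD with momentum and weight decay on per-pixel cross-entropy.

    Emits a checkpoint (deep parameter copy) every ``checkpoint_interval``
    iterations.  ``log_fn(iteration, loss, lr)`` is called each iteration if
    given.  Fully reproducible given ``cfg.seed``.
    """
    if train_set.n_slices == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(cfg.seed)
    velocity: dict[str, np.ndarray] = {}
    checkpoints: list[CheckpointRecord] = []
    n = train_set.n_slices
    cw = np.asarray(cfg.class_weights, dtype=np.float64) if cfg.class_weights else None

    for it in range(1, cfg.max_iterations + 1):
        idx = rng.integers(0, n, size=cfg.batch_size)
        imgs = np.stack([train_set.slice(i)[0] for i in idx]).astype(np.float32)
        labs = np.stack([train_set.slice(i)[1] for i in idx]).astype(np.intp)
        if cfg.augment_flips:
            flip = rng.random(cfg.batch_size) < 0.5
            imgs[flip] = imgs[flip, :, ::-1]
            labs[flip] = labs[flip, :, ::-1]
        grads, loss, _ = forward_backward(net, imgs, labs, class_weights=cw)
        if not math.isfinite(loss):
            raise RuntimeError(f"non-finite loss {loss} at iteration {it}; "
                               f"lower the learning rate")
        lr = cfg.lr_at(it - 1)
        for k, g in grads.items():
            p = net.params[k]
            if cfg.weight_decay and not k.endswith(".b"):
                g = g + cfg.weight_decay * p
            v = velocity.get(k)
            v = cfg.momentum * v - lr * g if v is not None else -lr * g
            velocity[k] = v
            net.params[k] = p + v
        if log_fn is not None:
            log_fn(it, loss, lr)
        if it % cfg.checkpoint_interval == 0:
            checkpoints.append(CheckpointRecord(iteration=it, params=net.copy_params(),
                                                arch=net.arch))
    return checkpoints


def _predict_case(net: NetworkInstance, images: np.ndarray,
                  chunk: int = 4) -> np.ndarray:
    """Slice-wise prediction of a (S, H, W) HU volume -> (S, H, W) labels."""
    out = []
    for s in range(0, images.shape[0], chunk):
        scores = forward(net, images[s:s + chunk].astype(np.float32))
        out.append(predict_labels(scores))
    return np.concatenate(out, axis=0)


def evaluate_case(net: NetworkInstance, case_id: str, images, masks,
                  foreground_classes) -> DiceReport:
    """Per-case Dice over the pooled voxels of all slices."""
    pred = _predict_case(net, images)
    return dice_report(pred, masks, foreground_classes, scope="case", case_id=case_id)


def _cohort_global(net: NetworkInstance, dataset: SliceDataset,
                   foreground_classes) -> tuple[float | None, list[DiceReport]]:
    reports = [evaluate_case(net, cid, img, msk, foreground_classes)
               for cid, img, msk in dataset.cases]
    cohort = aggregate_reports(reports)
    return cohort.global_dice, reports


def validate_checkpoints(checkpoints: list[CheckpointRecord], val_set: SliceDataset,
                         foreground_classes=None) -> DiceCurve:
    """Cohort global Dice of every checkpoint on the validation set."""
    if not checkpoints:
        raise ValueError("no checkpoints to validate")
    if val_set.n_slices == 0:
        raise ValueError("validation set is empty")
    arch = checkpoints[0].arch
    if foreground_classes is None:
        foreground_classes = list(range(1, arch.n_classes))
    net = init_network(arch, seed=0)
    points = []
    for rec in sorted(checkpoints, key=lambda r: r.iteration):
        net.load_params(rec.params)
        g, _ = _cohort_global(net, val_set, foreground_classes)
        g = 0.0 if g is None else g
        rec.validation_global_dice = g
        points.append((rec.iteration, g))
    return DiceCurve(points=points, variant=arch.variant)


def select_optimal(curve: DiceCurve, checkpoints: list[CheckpointRecord] | None = None):
    """Checkpoint (or curve point) with maximum global Dice; ties break to the
    earliest iteration."""
    if len(curve) == 0:
        raise ValueError("cannot select from an empty curve")
    best_it, _ = max(curve.points, key=lambda p: (p[1], -p[0]))
    if checkpoints is None:
        return next(p for p in curve.points if p[0] == best_it)
    for rec in sorted(checkpoints, key=lambda r: r.iteration):
        if rec.iteration == best_it:
            return rec
    raise ValueError(f"selected iteration {best_it} not among the checkpoints")


def evaluate_test(net: NetworkInstance, test_set: SliceDataset,
                  foreground_classes=None) -> tuple[DiceReport, list[DiceReport]]:
    """Cohort report + per-case reports on the test set."""
    if test_set.n_slices == 0:
        raise ValueError("test set is empty")
    if foreground_classes is None:
        foreground_classes = list(range(1, net.arch.n_classes))
    _, reports = _cohort_global(net, test_set, foreground_classes)
    return aggregate_reports(reports), reports
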