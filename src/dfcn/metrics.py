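"""Dice similarity evaluation: per structure, global (micro), and aggregated.

``dice(pred, ref, c)`` is 2|X∩Y| / (|X|+|Y|) over the pixel sets labelled
``c``; the 0/0 case (structure absent from both masks) yields ``None``, the
undefined sentinel, which aggregation excludes (with a surfaced count) rather
than silently scoring.  The global Dice is the class-wise micro average —
pooled intersection and size counts over all foreground classes — so a pixel
of one structure predicted as another structure earns no credit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["UNDEFINED", "DiceReport", "dice", "global_dice", "dice_report",
           "aggregate_reports", "class_counts"]

#: undefined-sentinel for 0/0 Dice
UNDEFINED = None


@dataclass
class DiceReport:
    """Per-structure and global Dice for one slice, case, or cohort."""

    per_class: dict[int, float | None]
    global_dice: float | None
    scope: str = "case"  # slice | case | cohort
    case_id: str | None = None
    n_cases: int = 1
    #: per class, how many cases were excluded as undefined (cohort scope)
    exclusions: dict[int, int] = field(default_factory=dict)

    def defined_classes(self) -> list[int]:
        return [c for c, v in self.per_class.items() if v is not None]


def _check_shapes(pred, ref) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError(f"mask shape mismatch: {pred.shape} vs {ref.shape}")
    return pred, ref


def class_counts(pred, ref, class_id: int) -> tuple[int, int, int]:
    """(|X|, |Y|, |X∩Y|) for one class."""
    pred, ref = _check_shapes(pred, ref)
    x = pred == class_id
    y = ref == class_id
    return int(x.sum()), int(y.sum()), int(np.logical_and(x, y).sum())


def dice(pred, ref, class_id: int) -> float | None:
    """Dice coefficient for one class; ``None`` when the class is absent from
    both masks (0/0)."""
    nx, ny, ni = class_counts(pred, ref, class_id)
    if nx + ny == 0:
        return UNDEFINED
    return 2.0 * ni / (nx + ny)


def global_dice(pred, ref, foreground_classes) -> float | None:
    """Micro-averaged Dice over the given classes: pooled counts
    (2 Σ|X_c∩Y_c|) / (Σ|X_c|+|Y_c|)."""
    foreground_classes = list(foreground_classes)
    if not foreground_classes:
        raise ValueError("foreground_classes must be non-empty")
    pred, ref = _check_shapes(pred, ref)
    num = den = 0
    for c in foreground_classes:
        nx, ny, ni = class_counts(pred, ref, c)
        num += 2 * ni
        den += nx + ny
    if den == 0:
        return UNDEFINED
    return num / den


def dice_report(pred, ref, foreground_classes, scope: str = "case",
                case_id: str | None = None) -> DiceReport:
    """Per-class and global Dice for one prediction/reference pair."""
    per_class = {c: dice(pred, ref, c) for c in foreground_classes}
    return DiceReport(per_class=per_class,
                      global_dice=global_dice(pred, ref, foreground_classes),
                      scope=scope, case_id=case_id)


def aggregate_reports(reports: list[DiceReport]) -> DiceReport:
    """Cohort aggregation: per-class mean over the cases where the class is
    defined (exclusion counts recorded), global = mean of per-case globals."""
    if not reports:
        raise ValueError("cannot aggregate an empty report list")
    classes = sorted({c for r in reports for c in r.per_class})
    per_class: dict[int, float | None] = {}
    exclusions: dict[int, int] = {}
    for c in classes:
        vals = [r.per_class[c] for r in reports if r.per_class.get(c) is not None]
        n_missing = sum(1 for r in reports if r.per_class.get(c) is None)
        per_class[c] = float(np.mean(vals)) if vals else UNDEFINED
        if n_missing:
            exclusions[c] = n_missing
    globals_ = [r.global_dice for r in reports if r.global_dice is not None]
    g = float(np.mean(globals_)) if globals_ else UNDEFINED
    return DiceReport(per_class=per_class, global_dice=g, scope="cohort",
                      n_cases=len(reports), exclusions=exclusions)
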