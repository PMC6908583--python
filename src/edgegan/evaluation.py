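"""Confusion-based metrics, grouped k-fold splits, imbalance resampling,
and fold-level report generation.

Metrics are reported on the percent scale with two-decimal rounding, the
convention of the classification tables this package reproduces.  The
positive class defaults to ``"tumor"`` when present, otherwise the
lexicographically first label; fold aggregation reports mean, sample
standard deviation (ddof=1) and median.
"""

from __future__ import annotations

import csv
import json
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidArgumentError
from .tiles import Tile

__all__ = [
    "ConfusionCounts",
    "FoldSplit",
    "EvaluationReport",
    "precision",
    "sensitivity",
    "f1",
    "confusion_from_labels",
    "kfold_by_group",
    "resample_imbalance",
    "evaluate_folds",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with an explicit positive class."""

    tp: int
    fp: int
    fn: int
    tn: int
    positive_label: str = "tumor"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InvalidArgumentError("confusion counts must be non-negative")


def _guarded_ratio(num: int, den: int) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return 100.0 * num / den, False


def precision(c: ConfusionCounts) -> float:
    """100 * tp / (tp + fp); 0 when the denominator is empty."""
    return _guarded_ratio(c.tp, c.tp + c.fp)[0]


def precision_flagged(c: ConfusionCounts) -> tuple[float, bool]:
    """Precision plus a flag marking a degenerate (empty) denominator."""
    return _guarded_ratio(c.tp, c.tp + c.fp)


def sensitivity(c: ConfusionCounts) -> float:
    """100 * tp / (tp + fn); 0 when the denominator is empty."""
    return _guarded_ratio(c.tp, c.tp + c.fn)[0]


def sensitivity_flagged(c: ConfusionCounts) -> tuple[float, bool]:
    return _guarded_ratio(c.tp, c.tp + c.fn)


def f1(p: float, s: float) -> float:
    """Harmonic mean of precision and sensitivity on the percent scale."""
    if not (0.0 <= p <= 100.0 and 0.0 <= s <= 100.0):
        raise InvalidArgumentError(f"precision/sensitivity must be in [0, 100], got {p}, {s}")
    if p + s == 0.0:
        return 0.0
    return 2.0 * p * s / (p + s)


def confusion_from_labels(y_true: Sequence[str], y_pred: Sequence[str],
                          positive_label: str) -> ConfusionCounts:
    if len(y_true) != len(y_pred):
        raise InvalidArgumentError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    tp = fp = fn = tn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive_label:
            if p == positive_label:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_label:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, positive_label=positive_label)


@dataclass(frozen=True)
class FoldSplit:
    """Assignment of group ids (slides) to fold indices 0..k-1."""

    assignments: dict[str, int]
    k: int

    def groups_in_fold(self, fold: int) -> list[str]:
        return sorted(g for g, f in self.assignments.items() if f == fold)

    def fold_of(self, group_id: str) -> int:
        return self.assignments[group_id]


def kfold_by_group(group_ids: Sequence[str], k: int, seed: int = 0) -> FoldSplit:
    """Shuffle unique groups by seed and partition them into k folds as
    evenly as possible; tiles must follow their group, so no group ever
    spans folds."""
    groups = sorted(set(group_ids))
    if k < 1:
        raise InvalidArgumentError(f"k must be >= 1, got {k}")
    if k > len(groups):
        raise InvalidArgumentError(
            f"k={k} exceeds the number of distinct groups ({len(groups)})"
        )
    rng = np.random.default_rng(seed)
    order = [groups[i] for i in rng.permutation(len(groups))]
    assignments: dict[str, int] = {}
    for fold, chunk in enumerate(np.array_split(np.arange(len(order)), k)):
        for i in chunk:
            assignments[order[int(i)]] = fold
    return FoldSplit(assignments=assignments, k=k)


def resample_imbalance(minority_tiles: list[Tile], majority_count: int,
                       ratio: float, seed: int = 0) -> list[Tile]:
    """Uniform subsample (without replacement) of floor(ratio * majority_count)
    minority tiles, emulating an artificial class imbalance."""
    if not 0.0 < ratio <= 1.0:
        raise InvalidArgumentError(f"ratio must be in (0, 1], got {ratio}")
    if majority_count < 0:
        raise InvalidArgumentError("majority_count must be >= 0")
    n_keep = int(ratio * majority_count)
    if n_keep > len(minority_tiles):
        raise InvalidArgumentError(
            f"requested {n_keep} tiles but only {len(minority_tiles)} available"
        )
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(minority_tiles), size=n_keep, replace=False).tolist())
    return [minority_tiles[i] for i in idx]


@dataclass
class EvaluationReport:
    """Per-fold and aggregate precision/sensitivity/F1 (percent, 2 dp)."""

    per_fold: list[dict] = field(default_factory=list)
    aggregate: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"per_fold": self.per_fold, "aggregate": self.aggregate,
                       "config": self.config}, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["fold", "precision", "sensitivity", "f1",
                             "tp", "fp", "fn", "tn"])
            for rec in self.per_fold:
                writer.writerow([rec["fold"], rec["precision"], rec["sensitivity"],
                                 rec["f1"], rec["tp"], rec["fp"], rec["fn"], rec["tn"]])


def _agg(values: list[float]) -> dict:
    return {
        "mean": round(float(np.mean(values)), 2),
        "sd": round(float(np.std(values, ddof=1)), 2) if len(values) > 1 else 0.0,
        "median": round(float(statistics.median(values)), 2),
    }


def evaluate_folds(registries: Mapping[int, object], fold_tiles: Mapping[int, list[Tile]],
                   metric: str = "mse", positive_label: str | None = None) -> EvaluationReport:
    """Classify each fold's tiles with that fold's registry and aggregate
    confusion metrics across folds.

    ``registries`` maps fold index to a trained ModelRegistry (one per
    fold); ``fold_tiles`` maps the same fold indices to labelled tiles.
    """
    from .classify import classify_tiles  # local import to avoid a cycle
    from .tiles import stack_pixels

    if set(registries) != set(fold_tiles):
        raise InvalidArgumentError(
            f"fold indices of registries {sorted(registries)} and tiles "
            f"{sorted(fold_tiles)} do not match"
        )
    all_labels = sorted({t.label for tiles in fold_tiles.values() for t in tiles})
    if positive_label is None:
        positive_label = "tumor" if "tumor" in all_labels else all_labels[0]

    per_fold: list[dict] = []
    for fold in sorted(registries):
        tiles = fold_tiles[fold]
        if not tiles:
            raise InvalidArgumentError(f"fold {fold} has no tiles")
        results = classify_tiles(registries[fold], stack_pixels(tiles), metric=metric)
        conf = confusion_from_labels([t.label for t in tiles],
                                     [r.predicted_label for r in results],
                                     positive_label)
        p = precision(conf)
        s = sensitivity(conf)
        per_fold.append({
            "fold": fold,
            "precision": round(p, 2), "sensitivity": round(s, 2),
            "f1": round(f1(p, s), 2),
            "tp": conf.tp, "fp": conf.fp, "fn": conf.fn, "tn": conf.tn,
        })
    aggregate = {
        "precision": _agg([r["precision"] for r in per_fold]),
        "sensitivity": _agg([r["sensitivity"] for r in per_fold]),
        "f1": _agg([r["f1"] for r in per_fold]),
    }
    return EvaluationReport(per_fold=per_fold, aggregate=aggregate,
                            config={"metric": metric, "positive_label": positive_label,
                                    "sd": "sample (ddof=1)"})
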