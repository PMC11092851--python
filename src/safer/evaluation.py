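"""Leakage-free splits, overall and per-triplet metrics, dose quadrants.

All samples of a (drug A, drug B, cell line) triplet share one fold so a
pair-cell combination never appears in both train and test.  Overall
AUPRC is step-wise average precision (no interpolation), which makes a
constant classifier score exactly the positive prevalence; AUROC follows
the Mann-Whitney convention with tied score pairs counting 0.5.
Per-triplet metrics recompute each metric within a triplet's dose
combinations and average across triplets.  IC50 values split each dose
axis into low (<= IC50) and high (> IC50), giving four dose quadrants.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "UndefinedMetricError",
    "PredictionSet",
    "DoseQuadrant",
    "group_kfold",
    "auprc",
    "auroc",
    "per_triplet_metrics",
    "assign_quadrant",
    "quadrant_metrics",
    "baseline_most_prevalent",
]


class UndefinedMetricError(ValueError):
    """A metric's preconditions (e.g. both classes present) are violated."""


class DoseQuadrant(enum.Enum):
    LOW = "low"
    LOW_HIGH = "low_high"
    HIGH = "high"
    HIGH_LOW = "high_low"


@dataclass
class PredictionSet:
    """Scores and labels with the keys every evaluation slices on."""

    scores: np.ndarray
    labels: np.ndarray
    triplets: list[tuple[str, str, str]]
    doses: list[tuple[float, float]] | None = None
    quadrants: list[DoseQuadrant | None] | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.scores)
        if len(self.labels) != n or len(self.triplets) != n:
            raise ValueError("prediction arrays are not aligned")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite prediction scores")

    def __len__(self) -> int:
        return len(self.scores)


def group_kfold(
    triplets: Sequence[tuple[str, str, str]], n_folds: int = 10, seed: int = 0
) -> np.ndarray:
    """Assign each sample a test fold such that triplets never split.

    Distinct triplets are shuffled with ``seed`` and dealt round-robin,
    so fold sizes (in triplets) differ by at most one.
    """
    unique = sorted(set(triplets))
    if len(unique) < n_folds:
        raise ValueError(f"{len(unique)} triplets cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    fold_of = {unique[j]: int(i % n_folds) for i, j in enumerate(order)}
    return np.array([fold_of[t] for t in triplets], dtype=int)


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Step-wise average precision; requires at least one positive."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise UndefinedMetricError("average precision undefined without positives")
    return float(average_precision_score(labels, scores))


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUROC (ties 0.5); requires both classes."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUROC undefined with a single class")
    return float(roc_auc_score(labels, scores))


@dataclass
class PerTripletResult:
    """Mean and sd of a metric over triplet groups, with skip accounting."""

    mean: float
    sd: float
    n_groups: int
    n_skipped: int


def per_triplet_metrics(preds: PredictionSet) -> dict[str, PerTripletResult]:
    """AUPRC and AUROC within each triplet group, then averaged.

    A group without positives is skipped for AUPRC, a single-class group
    for AUROC; skip counts are reported alongside the means.
    """
    groups: dict[tuple[str, str, str], list[int]] = {}
    for i, t in enumerate(preds.triplets):
        groups.setdefault(t, []).append(i)
    out: dict[str, PerTripletResult] = {}
    for name, metric in (("auprc", auprc), ("auroc", auroc)):
        values = []
        skipped = 0
        for idx in groups.values():
            idx = np.asarray(idx)
            try:
                values.append(metric(preds.scores[idx], preds.labels[idx]))
            except UndefinedMetricError:
                skipped += 1
        if not values:
            raise UndefinedMetricError(f"no triplet group supports {name}")
        out[name] = PerTripletResult(
            mean=float(np.mean(values)),
            sd=float(np.std(values)),
            n_groups=len(values),
            n_skipped=skipped,
        )
    return out


def assign_quadrant(
    drug_a: str,
    drug_b: str,
    cell: str,
    dose_a: float,
    dose_b: float,
    ic50: Mapping[tuple[str, str], float],
) -> DoseQuadrant | None:
    """Classify a dose pair against the two drugs' IC50 in that cell line.

    A dose strictly above the IC50 is "high"; a dose equal to the IC50
    counts as low.  Returns ``None`` when either IC50 is missing, so the
    caller can count exclusions.
    """
    key_a, key_b = (drug_a, cell), (drug_b, cell)
    if key_a not in ic50 or key_b not in ic50:
        return None
    high_a = dose_a > ic50[key_a]
    high_b = dose_b > ic50[key_b]
    if high_a and high_b:
        return DoseQuadrant.HIGH
    if high_a:
        return DoseQuadrant.HIGH_LOW
    if high_b:
        return DoseQuadrant.LOW_HIGH
    return DoseQuadrant.LOW


def quadrant_metrics(
    preds: PredictionSet, ic50: Mapping[tuple[str, str], float]
) -> dict[str, dict]:
    """Overall AUPRC/AUROC inside each dose quadrant.

    Samples without IC50 coverage are excluded and counted; the four
    quadrant counts plus the exclusions partition the input.
    """
    if preds.doses is None:
        raise ValueError("quadrant analysis needs dose pairs on the prediction set")
    assignments: list[DoseQuadrant | None] = []
    for (a, b, cell), (da, db) in zip(preds.triplets, preds.doses):
        assignments.append(assign_quadrant(a, b, cell, da, db, ic50))
    preds.quadrants = assignments
    out: dict[str, dict] = {"excluded_missing_ic50": int(sum(q is None for q in assignments))}
    for quadrant in DoseQuadrant:
        idx = np.array([i for i, q in enumerate(assignments) if q is quadrant], dtype=int)
        block: dict = {"n": int(len(idx))}
        if len(idx):
            for name, metric in (("auprc", auprc), ("auroc", auroc)):
                try:
                    block[name] = metric(preds.scores[idx], preds.labels[idx])
                except UndefinedMetricError:
                    block[name] = None
        out[quadrant.value] = block
    return out


def baseline_most_prevalent(train_labels: np.ndarray) -> float:
    """Constant score of the most-prevalent-label baseline.

    The baseline emits one constant for every sample (the positive-class
    prevalence of the training labels); under the step-wise AP and the
    tie-0.5 AUROC conventions its AUPRC equals the test prevalence and
    its AUROC is exactly 0.5.
    """
    train_labels = np.asarray(train_labels)
    if len(train_labels) == 0:
        raise ValueError("empty label vector")
    return float(train_labels.mean())
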