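"""Comparison of predictions with LLNA references.

Contingency tables at three nested granularities (4-class, UN GHS, binary
hazard; the coarser tables are collapses of the finer one, so accuracy can
only rise when collapsing), the usual classification metrics, PoD-vs-EC3
conservatism statistics, and stratified k-fold cross-validation of the full
train-predict pipeline.

The PoD/EC3 ratio bands follow the reproducibility of the LLNA itself:
ratios within 10**0.5-fold of unity (0.316 to 3.16, endpoints inclusive)
count as "similar"; below as "more conservative" (the prediction would
protect more); above as "less conservative".  The geometric mean fold
error, GMFE = 10**mean(|log10(PoD/EC3)|), summarizes the spread; it is 1
exactly when every ratio is 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import workflow
from .data_model import (
    GHSCategory,
    HazardClass,
    PotencyClass,
    SubstanceRecord,
    ValidationError,
    collapse_to_ghs,
    collapse_to_hazard,
)
from .potency import predicted_class

__all__ = [
    "ContingencyTable",
    "Metrics",
    "PodComparison",
    "CVResult",
    "GRANULARITIES",
    "SIMILAR_BAND",
    "contingency",
    "metrics",
    "pod_comparison",
    "stratified_cv",
]

GRANULARITIES = ("four_class", "ghs", "hazard")

#: Default "similar" band for PoD/EC3 ratios (10**-0.5 to 10**0.5).
SIMILAR_BAND = (0.316, 3.16)

_LABELS = {
    "four_class": tuple(c.label for c in PotencyClass),
    "ghs": tuple(c.label for c in GHSCategory),
    "hazard": tuple(c.label for c in HazardClass),
}
_COLLAPSE = {
    "four_class": lambda c: int(c),
    "ghs": lambda c: int(collapse_to_ghs(c)),
    "hazard": lambda c: int(collapse_to_hazard(c)),
}


@dataclass
class ContingencyTable:
    """Predicted (rows) x reference (columns) counts at one granularity."""

    granularity: str
    counts: np.ndarray
    labels: tuple[str, ...]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.labels, name="predicted"),
            columns=pd.Index(self.labels, name="reference"),
        )


@dataclass
class Metrics:
    """Classification metrics of one contingency table.

    ``sensitivity``/``specificity``/``balanced_accuracy`` are only defined
    for hazard tables; a metric whose reference margin is empty is reported
    as None and listed in ``undefined`` rather than silently zeroed.
    """

    accuracy: float
    n: int
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    balanced_accuracy: Optional[float] = None
    undefined: tuple[str, ...] = ()


def contingency(
    predictions: Sequence[PotencyClass],
    references: Sequence[PotencyClass],
    granularity: str = "four_class",
) -> ContingencyTable:
    """Count (collapsed prediction, collapsed reference) pairs."""
    if granularity not in GRANULARITIES:
        raise ValidationError(f"unknown granularity {granularity!r}")
    if len(predictions) != len(references):
        raise ValidationError("predictions and references differ in length")
    if len(predictions) == 0:
        raise ValidationError("cannot build a contingency table from zero pairs")
    collapse = _COLLAPSE[granularity]
    labels = _LABELS[granularity]
    k = len(labels)
    counts = np.zeros((k, k), dtype=int)
    for pred, ref in zip(predictions, references):
        counts[collapse(PotencyClass(pred)), collapse(PotencyClass(ref))] += 1
    return ContingencyTable(granularity=granularity, counts=counts, labels=labels)


def metrics(table: ContingencyTable) -> Metrics:
    """Accuracy; plus sensitivity/specificity/balanced for hazard tables."""
    counts = table.counts
    total = table.total
    if total == 0:
        raise ValidationError("empty contingency table")
    accuracy = float(np.trace(counts) / total)
    if table.granularity != "hazard":
        return Metrics(accuracy=accuracy, n=total)
    undefined = []
    ref_ns = counts[:, 0].sum()
    ref_s = counts[:, 1].sum()
    specificity = sensitivity = balanced = None
    if ref_ns > 0:
        specificity = float(counts[0, 0] / ref_ns)
    else:
        undefined.append("specificity")
    if ref_s > 0:
        sensitivity = float(counts[1, 1] / ref_s)
    else:
        undefined.append("sensitivity")
    if specificity is not None and sensitivity is not None:
        balanced = (specificity + sensitivity) / 2.0
    else:
        undefined.append("balanced_accuracy")
    return Metrics(
        accuracy=accuracy,
        n=total,
        sensitivity=sensitivity,
        specificity=specificity,
        balanced_accuracy=balanced,
        undefined=tuple(undefined),
    )


@dataclass
class PodComparison:
    """Per-substance PoD/EC3 ratios with conservatism summary statistics."""

    table: pd.DataFrame  # columns: pod_bn, ec3, ratio, category
    counts: dict[str, int]
    gmfe: float
    pearson_r: Optional[float]
    spearman_rho: Optional[float]


def pod_comparison(
    pods: Sequence[float],
    ec3s: Sequence[float],
    similar_band: tuple[float, float] = SIMILAR_BAND,
    log_scale_pearson: bool = False,
) -> PodComparison:
    """Ratio-based conservatism analysis of predicted PoDs against EC3s.

    Band endpoints are inclusive for "similar".  Pearson is computed on the
    raw percent values by default (``log_scale_pearson`` switches to log10,
    the fold-change scale); Spearman is rank-based and transform-invariant.
    """
    pod_arr = np.asarray(pods, dtype=float)
    ec3_arr = np.asarray(ec3s, dtype=float)
    if pod_arr.shape != ec3_arr.shape or pod_arr.ndim != 1:
        raise ValidationError("pods and ec3s must be equal-length 1-d sequences")
    if pod_arr.size == 0:
        raise ValidationError("no PoD/EC3 pairs")
    if np.any(pod_arr <= 0) or np.any(ec3_arr <= 0):
        raise ValidationError("PoD and EC3 values must be strictly positive")
    low, high = similar_band
    ratio = pod_arr / ec3_arr
    category = np.where(
        ratio < low,
        "more_conservative",
        np.where(ratio > high, "less_conservative", "similar"),
    )
    table = pd.DataFrame(
        {"pod_bn": pod_arr, "ec3": ec3_arr, "ratio": ratio, "category": category}
    )
    counts = {
        name: int((category == name).sum())
        for name in ("more_conservative", "similar", "less_conservative")
    }
    gmfe = float(10.0 ** np.mean(np.abs(np.log10(ratio))))
    pearson_r = spearman_rho = None
    if pod_arr.size >= 2:
        x, y = (np.log10(pod_arr), np.log10(ec3_arr)) if log_scale_pearson else (
            pod_arr,
            ec3_arr,
        )
        if np.ptp(x) > 0 and np.ptp(y) > 0:
            pearson_r = float(stats.pearsonr(x, y).statistic)
            spearman_rho = float(stats.spearmanr(pod_arr, ec3_arr).statistic)
    return PodComparison(
        table=table,
        counts=counts,
        gmfe=gmfe,
        pearson_r=pearson_r,
        spearman_rho=spearman_rho,
    )


@dataclass
class CVResult:
    fold_accuracies: tuple[float, ...]
    mean_accuracy: float
    fold_assignment: tuple[int, ...]  # fold index of each input record


def _stratified_folds(
    labels: Sequence[PotencyClass], k: int, rng: np.random.Generator
) -> np.ndarray:
    """Deterministic stratified fold assignment, round-robin within class."""
    folds = np.empty(len(labels), dtype=int)
    counter = 0
    for cls in PotencyClass:
        members = np.flatnonzero(np.asarray([int(l) for l in labels]) == int(cls))
        if members.size == 0:
            continue
        members = rng.permutation(members)
        for idx in members:
            folds[idx] = counter % k
            counter += 1
    return folds


def stratified_cv(
    records: Sequence[SubstanceRecord],
    model_config: Optional[Mapping] = None,
    k: int = 5,
    seed: int = 0,
    **train_kwargs,
) -> CVResult:
    """k-fold cross-validated 4-class accuracy of the full pipeline.

    Folds are stratified by reference class (per-fold class counts within
    one of exact proportionality); each fold's model is trained from
    scratch -- discretization included -- on the remaining records.
    ``train_kwargs`` are forwarded to :func:`skinbn.workflow.train_model`.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    n = len(records)
    if n < k:
        raise ValidationError(f"need at least k={k} records, got {n}")
    labels = [rec.reference_class() for rec in records]
    class_counts = np.bincount([int(l) for l in labels], minlength=4)
    if np.any((class_counts > 0) & (class_counts < k)):
        warnings.warn(
            "fewer records than folds in some class: stratification is reduced",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(labels, k, rng)

    accuracies = []
    for fold in range(k):
        test_idx = np.flatnonzero(folds == fold)
        train_idx = np.flatnonzero(folds != fold)
        model = workflow.train_model(
            [records[i] for i in train_idx],
            config=model_config,
            seed=seed + fold,
            **train_kwargs,
        )
        correct = 0
        for i in test_idx:
            profile = workflow.predict_profile(model, records[i])
            if predicted_class(profile) == labels[i]:
                correct += 1
        accuracies.append(correct / len(test_idx) if len(test_idx) else float("nan"))
    acc = tuple(float(a) for a in accuracies)
    return CVResult(
        fold_accuracies=acc,
        mean_accuracy=float(np.nanmean(acc)),
        fold_assignment=tuple(int(f) for f in folds),
    )
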