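"""Supervised discretization of quantitative inputs (Fayyad-Irani MDLPC).

Quantitative assay values enter the discrete network as 2-3 ordered
categories.  Cut points are chosen against the 4-class potency label by
recursive entropy-minimizing binary splitting: at each step the candidate
boundary with maximal class-information gain is taken, and the split is kept
only if the gain exceeds the Minimum Description Length (MDL) cost of
encoding the extra partition,

    gain > [log2(N - 1) + log2(3^k - 2) - (k*Ent(S) - k1*Ent(S1) - k2*Ent(S2))] / N,

where N = |S| and k, k1, k2 are the numbers of distinct classes in the
parent and child partitions.  Candidate cuts are midpoints between adjacent
distinct values whose class composition differs, which provably contains the
entropy-optimal cut.  Recursion is capped so at most ``max_bins`` categories
result; when the criterion would accept more, the splits with the largest
information gain are kept.

Intervals are half-open [low, high): a value equal to a threshold belongs to
the upper category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data_model import ValidationError

__all__ = ["DiscretizationSpec", "mdl_discretize", "apply_thresholds"]


@dataclass(frozen=True)
class DiscretizationSpec:
    """Cut values partitioning one quantitative variable into categories."""

    variable_name: str
    thresholds: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        ts = tuple(float(t) for t in self.thresholds)
        object.__setattr__(self, "thresholds", ts)
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValidationError(
                f"{self.variable_name}: thresholds must be strictly increasing"
            )

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _best_cut(values: np.ndarray, codes: np.ndarray, n_classes: int):
    """Best boundary cut of a sorted slice by information gain.

    Returns ``(cut_value, gain, left_size)`` or ``None`` if no candidate
    exists.  ``values`` must be sorted ascending; ``codes`` are class codes.
    """
    n = len(values)
    # prefix class counts: counts[i] = class histogram of values[:i]
    one_hot = np.zeros((n + 1, n_classes))
    one_hot[np.arange(1, n + 1), codes] = 1.0
    prefix = one_hot.cumsum(axis=0)
    total = prefix[-1]
    ent_total = _entropy(total)

    best = None
    for i in range(1, n):
        if values[i - 1] == values[i]:
            continue
        # skip non-boundary cuts: both neighbouring value-groups pure in the
        # same single class
        left_group = codes[values == values[i - 1]]
        right_group = codes[values == values[i]]
        if (
            left_group[0] == right_group[0]
            and np.all(left_group == left_group[0])
            and np.all(right_group == right_group[0])
        ):
            continue
        left = prefix[i]
        right = total - left
        gain = ent_total - (i / n) * _entropy(left) - ((n - i) / n) * _entropy(right)
        if best is None or gain > best[1] + 1e-12:
            cut = (values[i - 1] + values[i]) / 2.0
            best = (cut, gain, i, left, right, ent_total)
    return best


def _mdl_accepts(n, gain, left, right, total_counts, ent_total) -> bool:
    k = int((total_counts > 0).sum())
    k1 = int((left > 0).sum())
    k2 = int((right > 0).sum())
    delta = math.log2(3**k - 2) - (
        k * ent_total - k1 * _entropy(left) - k2 * _entropy(right)
    )
    threshold = (math.log2(n - 1) + delta) / n
    return gain > threshold


def mdl_discretize(
    values: Sequence[float],
    labels: Sequence,
    max_bins: int = 3,
    variable_name: str = "",
) -> DiscretizationSpec:
    """Fit MDLPC cut points for one variable against the class labels.

    Missing values must be excluded by the caller.  Labels may be any
    hashable class identifiers.  All-identical labels or fewer than two
    distinct values yield an empty (single-category) spec.  The procedure is
    deterministic: identical data always produce identical cuts.
    """
    vals = np.asarray(values, dtype=float)
    labs = np.asarray(labels)
    if len(vals) != len(labs):
        raise ValidationError("values and labels must have the same length")
    if len(vals) < 2:
        return DiscretizationSpec(variable_name)
    if max_bins < 1:
        raise ValidationError("max_bins must be >= 1")

    classes, codes = np.unique(labs, return_inverse=True)
    if len(classes) < 2 or len(np.unique(vals)) < 2:
        return DiscretizationSpec(variable_name)

    order = np.argsort(vals, kind="stable")
    vals = vals[order]
    codes = codes[order]
    n_classes = len(classes)

    accepted: list[tuple[float, float]] = []  # (cut, gain at acceptance)

    def recurse(lo: int, hi: int) -> None:
        seg_vals = vals[lo:hi]
        seg_codes = codes[lo:hi]
        n = hi - lo
        if n < 2:
            return
        best = _best_cut(seg_vals, seg_codes, n_classes)
        if best is None:
            return
        cut, gain, split, left, right, ent_total = best
        total_counts = left + right
        if not _mdl_accepts(n, gain, left, right, total_counts, ent_total):
            return
        accepted.append((cut, gain))
        recurse(lo, lo + split)
        recurse(lo + split, hi)

    recurse(0, len(vals))

    if len(accepted) > max_bins - 1:
        accepted.sort(key=lambda item: (-item[1], item[0]))
        accepted = accepted[: max_bins - 1]
    thresholds = tuple(sorted(cut for cut, _ in accepted))
    return DiscretizationSpec(variable_name, thresholds)


def apply_thresholds(value: Optional[float], spec: DiscretizationSpec) -> Optional[int]:
    """Category index of ``value`` under ``spec`` (None stays None).

    Half-open-left convention: category i covers [t_{i-1}, t_i); a value
    equal to a threshold falls in the upper category.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return int(np.searchsorted(np.asarray(spec.thresholds), float(value), side="right"))
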