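"""Contingency tables, published metrics, PoD/EC3 conservatism, CV."""

import numpy as np
import pytest

from skinbn.data_model import PotencyClass, ValidationError
from skinbn.evaluation import (
    contingency,
    metrics,
    pod_comparison,
    stratified_cv,
)
from skinbn.synthetic_data import GeneratorConfig, generate_substances

from conftest import TEST_4CLASS, TRAIN_4CLASS, pairs_from_matrix

TRAIN_GHS = np.array([[55, 19, 1], [11, 44, 12], [3, 23, 51]])
TRAIN_HAZARD = np.array([[55, 20], [14, 130]])


def test_training_set_tables_and_metrics():
    preds, refs = pairs_from_matrix(TRAIN_4CLASS)
    four = contingency(preds, refs, "four_class")
    assert np.array_equal(four.counts, TRAIN_4CLASS)
    assert round(100 * metrics(four).accuracy) == 64

    ghs = contingency(preds, refs, "ghs")
    assert np.array_equal(ghs.counts, TRAIN_GHS)
    assert round(100 * metrics(ghs).accuracy) == 68

    hazard = contingency(preds, refs, "hazard")
    assert np.array_equal(hazard.counts, TRAIN_HAZARD)
    m = metrics(hazard)
    assert round(100 * m.accuracy) == 84
    assert m.specificity == pytest.approx(55 / 69)
    assert m.sensitivity == pytest.approx(130 / 150)
    assert round(100 * m.balanced_accuracy, 1) == 83.2


def test_test_set_metrics():
    preds, refs = pairs_from_matrix(TEST_4CLASS)
    assert round(100 * metrics(contingency(preds, refs, "four_class")).accuracy) == 53
    assert round(100 * metrics(contingency(preds, refs, "ghs")).accuracy) == 63
    m = metrics(contingency(preds, refs, "hazard"))
    assert round(100 * m.accuracy) == 86
    assert round(100 * m.balanced_accuracy, 1) == 82.7


def test_combined_set_metrics():
    tp, tr = pairs_from_matrix(TRAIN_4CLASS)
    sp, sr = pairs_from_matrix(TEST_4CLASS)
    preds, refs = tp + sp, tr + sr
    assert len(preds) == 297
    assert round(100 * metrics(contingency(preds, refs, "four_class")).accuracy) == 61
    assert round(100 * metrics(contingency(preds, refs, "ghs")).accuracy) == 67
    assert round(100 * metrics(contingency(preds, refs, "hazard")).accuracy) == 85


def _collapse_matrix(counts: np.ndarray, groups) -> np.ndarray:
    k = len(groups)
    out = np.zeros((k, k), dtype=int)
    for i, gi in enumerate(groups):
        for j, gj in enumerate(groups):
            out[i, j] = counts[np.ix_(gi, gj)].sum()
    return out


@pytest.mark.parametrize("trial", range(10))
def test_collapsing_commutes_with_counting(trial):
    """ghs/hazard tables == the collapsed four-class table."""
    rng = np.random.default_rng(4000 + trial)
    preds = [PotencyClass(int(v)) for v in rng.integers(0, 4, size=60)]
    refs = [PotencyClass(int(v)) for v in rng.integers(0, 4, size=60)]
    four = contingency(preds, refs, "four_class").counts
    ghs = contingency(preds, refs, "ghs").counts
    hazard = contingency(preds, refs, "hazard").counts
    assert np.array_equal(ghs, _collapse_matrix(four, [[0], [1, 2], [3]]))
    assert np.array_equal(hazard, _collapse_matrix(four, [[0], [1, 2, 3]]))


@pytest.mark.parametrize("trial", range(10))
def test_accuracy_monotone_under_collapsing(trial):
    """Merging classes never un-corrects a correct prediction."""
    rng = np.random.default_rng(5000 + trial)
    preds = [PotencyClass(int(v)) for v in rng.integers(0, 4, size=80)]
    refs = [PotencyClass(int(v)) for v in rng.integers(0, 4, size=80)]
    acc = {
        g: metrics(contingency(preds, refs, g)).accuracy
        for g in ("four_class", "ghs", "hazard")
    }
    assert acc["hazard"] >= acc["ghs"] >= acc["four_class"]


def test_contingency_errors():
    with pytest.raises(ValidationError):
        contingency([], [], "four_class")
    with pytest.raises(ValidationError):
        contingency([PotencyClass.NS], [], "four_class")
    with pytest.raises(ValidationError):
        contingency([PotencyClass.NS], [PotencyClass.NS], "bogus")


def test_undefined_metrics_are_flagged():
    preds = [PotencyClass.WEAK, PotencyClass.MODERATE]
    refs = [PotencyClass.WEAK, PotencyClass.STRONG_EXTREME]
    m = metrics(contingency(preds, refs, "hazard"))  # no NS references
    assert m.specificity is None
    assert "specificity" in m.undefined and "balanced_accuracy" in m.undefined
    assert m.sensitivity == pytest.approx(1.0)


def test_pod_comparison_worked_pairs():
    result = pod_comparison([8.73, 20.88], [8.6, 0.003])
    assert result.table["ratio"].iloc[0] == pytest.approx(1.015, abs=2e-3)
    assert result.table["category"].iloc[0] == "similar"
    assert result.table["ratio"].iloc[1] == pytest.approx(6960.0)
    assert result.table["category"].iloc[1] == "less_conservative"


def test_pod_comparison_identity():
    pods = [0.5, 3.0, 40.0, 90.0]
    result = pod_comparison(pods, pods)
    assert result.counts == {
        "more_conservative": 0,
        "similar": 4,
        "less_conservative": 0,
    }
    assert result.gmfe == pytest.approx(1.0)
    assert result.pearson_r == pytest.approx(1.0)
    assert result.spearman_rho == pytest.approx(1.0)


def test_band_endpoints_inclusive():
    result = pod_comparison([0.316, 3.16, 0.315, 3.17], [1.0, 1.0, 1.0, 1.0])
    assert list(result.table["category"]) == [
        "similar",
        "similar",
        "more_conservative",
        "less_conservative",
    ]


def test_gmfe_properties():
    rng = np.random.default_rng(8)
    pods = 10 ** rng.uniform(-0.5, 2, size=50)
    ec3s = 10 ** rng.uniform(-3, 2, size=50)
    result = pod_comparison(pods, ec3s)
    assert result.gmfe >= 1.0
    with pytest.raises(ValidationError):
        pod_comparison([1.0, -2.0], [1.0, 1.0])


def test_excluding_extreme_ec3_keeps_conservative_count():
    """Dropping pairs with EC3 < 0.2 (below the PoD floor) cannot change the
    more-conservative count: those ratios always exceed 1."""
    rng = np.random.default_rng(99)
    pods = 10 ** rng.uniform(np.log10(0.2), 2, size=200)
    ec3s = 10 ** rng.uniform(np.log10(0.0003), 2, size=200)
    full = pod_comparison(pods, ec3s)
    keep = ec3s >= 0.2
    reduced = pod_comparison(pods[keep], ec3s[keep])
    assert (
        reduced.counts["more_conservative"] == full.counts["more_conservative"]
    )
    assert reduced.counts["less_conservative"] <= full.counts["less_conservative"]


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def test_stratified_folds_partition_and_proportions():
    records = generate_substances(GeneratorConfig(n=120, seed=3))
    labels = np.array([int(r.reference_class()) for r in records])
    result = stratified_cv(records, k=4, seed=1, max_iter=2, tol=1.0)
    folds = np.array(result.fold_assignment)
    assert folds.shape == (120,)
    assert set(folds) == {0, 1, 2, 3}
    for cls in range(4):
        per_fold = np.bincount(folds[labels == cls], minlength=4)
        assert per_fold.max() - per_fold.min() <= 1
    assert len(result.fold_accuracies) == 4


def test_cv_recovers_signal_above_chance():
    """Well-separated synthetic data: mean 4-class accuracy beats 25%."""
    records = generate_substances(GeneratorConfig(n=300, seed=7))
    result = stratified_cv(records, k=5, seed=7, max_iter=40, tol=1e-3)
    assert result.mean_accuracy > 0.25
    assert result.mean_accuracy > 0.4  # default separation is far from chance


def test_leave_one_out_degenerate():
    records = generate_substances(GeneratorConfig(n=10, seed=13))
    with pytest.warns(UserWarning):
        result = stratified_cv(records, k=10, seed=0, max_iter=2, tol=1.0)
    assert len(result.fold_accuracies) == 10
    assert sorted(result.fold_assignment) == list(range(10))


def test_cv_validation():
    records = generate_substances(GeneratorConfig(n=10, seed=13))
    with pytest.raises(ValidationError):
        stratified_cv(records, k=1)
    with pytest.raises(ValidationError):
        stratified_cv(records, k=11)
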