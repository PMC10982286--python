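"""AUC, DeLong CI, multiclass averaging, confusion, Youden metrics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mltriss.categories import GCS_CATEGORIES, GCS_POINTS_CATEGORIES, ISS_CATEGORIES
from mltriss.evaluation import (
    auc_ci,
    binary_auc,
    confusion,
    multiclass_auc,
    youden_metrics,
)


def brute_force_auc(scores, labels):
    """Concordant-pair counting, ties half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (pos.size * neg.size)


def test_auc_perfect_separation():
    assert binary_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0


def test_auc_all_ties():
    assert binary_auc([0.5] * 10, [1] * 5 + [0] * 5) == 0.5


def test_auc_toy_three_quarters():
    assert binary_auc([0.9, 0.8, 0.7, 0.85], [1, 1, 0, 0]) == pytest.approx(0.75)


def test_auc_matches_brute_force(rng):
    for _ in range(25):
        n = int(rng.integers(6, 40))
        scores = rng.choice(np.linspace(0, 1, 11), n)  # force ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            continue
        assert binary_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )


def test_auc_single_class_errors():
    with pytest.raises(ValueError):
        binary_auc([0.2, 0.8], [1, 1])


def test_auc_antisymmetry(rng):
    scores = rng.normal(size=60)  # continuous, no ties
    labels = rng.random(60) < 0.4
    labels[0] = True
    labels[1] = False
    assert binary_auc(scores, labels) + binary_auc(-scores, labels) == pytest.approx(1.0)


@given(st.integers(1, 6))
@settings(max_examples=10, deadline=None)
def test_auc_monotone_transform_invariance(power):
    rng = np.random.default_rng(3)
    scores = rng.uniform(0.1, 2.0, 80)
    labels = rng.random(80) < 0.5
    if labels.all() or not labels.any():
        return
    a = binary_auc(scores, labels)
    assert binary_auc(scores**power, labels) == pytest.approx(a, abs=1e-12)
    assert binary_auc(np.log(scores), labels) == pytest.approx(a, abs=1e-12)


def test_weighted_auc_equals_replication(rng):
    """Integer weights reproduce the AUC of the replicated sample."""
    scores = rng.choice(np.linspace(0, 1, 7), 20)
    labels = np.r_[np.ones(8, bool), np.zeros(12, bool)]
    w = rng.integers(1, 4, 20)
    rep_scores = np.repeat(scores, w)
    rep_labels = np.repeat(labels, w)
    assert binary_auc(scores, labels, sample_weight=w) == pytest.approx(
        binary_auc(rep_scores, rep_labels), abs=1e-12
    )


# ---------------------------------------------------------------------------
# confidence intervals
# ---------------------------------------------------------------------------


def test_delong_ci_narrow_for_separated_large_n(rng):
    scores = np.r_[rng.normal(2.0, 0.5, 1500), rng.normal(0.0, 0.5, 1500)]
    labels = np.r_[np.ones(1500, bool), np.zeros(1500, bool)]
    lo, hi = auc_ci(scores, labels)
    assert hi - lo < 0.05
    assert lo <= binary_auc(scores, labels) <= hi


def test_delong_matches_bootstrap(rng):
    scores = np.r_[rng.normal(1.0, 1.0, 60), rng.normal(0.0, 1.0, 80)]
    labels = np.r_[np.ones(60, bool), np.zeros(80, bool)]
    d_lo, d_hi = auc_ci(scores, labels, method="delong")
    b_lo, b_hi = auc_ci(scores, labels, method="bootstrap", n_boot=4000, seed=9)
    assert abs(d_lo - b_lo) < 0.02
    assert abs(d_hi - b_hi) < 0.02


def test_null_auc_ci_covers_half(rng):
    scores = rng.normal(size=400)
    labels = rng.random(400) < 0.5
    lo, hi = auc_ci(scores, labels)
    assert lo < 0.5 < hi


def test_ci_clipped_to_unit_interval():
    lo, hi = auc_ci([3.0, 2.0, 1.0, 0.0], [1, 1, 0, 0])
    assert 0.0 <= lo <= hi <= 1.0


# ---------------------------------------------------------------------------
# multiclass AUC
# ---------------------------------------------------------------------------


def _pooled_micro_oracle(P, labels, classes):
    onehot = (np.asarray(labels)[:, None] == np.asarray(classes)[None, :]).astype(float)
    return brute_force_auc(P.ravel(), onehot.ravel().astype(bool))


def test_two_balanced_classes_macro_equals_micro_equals_binary(rng):
    # balanced classes with a symmetric classifier (class-0 scores mirror
    # class-1 scores), where the pooled micro average reduces exactly
    u = rng.uniform(0.05, 0.95, 30)
    p1 = np.concatenate([u, 1 - u])
    labels = np.r_[np.ones(30, int), np.zeros(30, int)]
    P = np.column_stack([1 - p1, p1])
    rep = multiclass_auc(P, labels, [0, 1])
    b = binary_auc(p1, labels == 1)
    assert rep.macro == pytest.approx(b, abs=1e-12)
    assert rep.micro == pytest.approx(b, abs=1e-12)


def test_perfect_classifier_all_ones():
    labels = np.array([0, 1, 2, 0, 1, 2, 2])
    P = np.zeros((7, 3))
    P[np.arange(7), labels] = 1.0
    rep = multiclass_auc(P, labels, [0, 1, 2])
    assert rep.macro == 1.0
    assert rep.micro == 1.0
    assert all(v == 1.0 for v in rep.per_class.values())


def test_micro_equals_pooled_oracle(rng):
    n, k = 17, 3
    P = rng.dirichlet(np.ones(k), n)
    labels = rng.integers(0, k, n)
    labels[:k] = np.arange(k)  # ensure all present
    rep = multiclass_auc(P, labels, np.arange(k))
    assert rep.micro == pytest.approx(
        _pooled_micro_oracle(P, labels, np.arange(k)), abs=1e-12
    )


def test_absent_class_excluded_from_macro(rng):
    P = rng.dirichlet(np.ones(3), 12)
    labels = np.r_[np.zeros(6, int), np.ones(6, int)]  # class 2 absent
    rep = multiclass_auc(P, labels, [0, 1, 2])
    assert rep.absent_classes == [2]
    assert set(rep.per_class) == {0, 1}


def test_invalid_simplex_rejected(rng):
    P = np.full((4, 3), 0.5)
    with pytest.raises(ValueError):
        multiclass_auc(P, [0, 1, 2, 0], [0, 1, 2])


# ---------------------------------------------------------------------------
# confusion
# ---------------------------------------------------------------------------


def test_confusion_perfect_prediction():
    truth = np.array([3, 5, 10, 14, 15, 8])
    mat, tpr = confusion(truth, truth, GCS_CATEGORIES)
    assert np.all(np.asarray(mat)[np.eye(3, dtype=bool)] == np.diag(mat))
    assert mat.to_numpy().sum() == 6
    assert np.nansum(tpr.to_numpy()) == pytest.approx(
        np.isfinite(tpr.to_numpy()).sum()
    )


def test_confusion_constant_predictor_mass_in_mild_column():
    truth = np.array([3, 6, 10, 14, 15, 13])
    pred = np.full(6, 15)
    mat, tpr = confusion(pred, truth, GCS_CATEGORIES)
    assert mat["mild"].sum() == 6
    assert tpr["mild"] == 1.0
    assert tpr["severe"] == 0.0


def test_iss_category_boundaries():
    mat, _ = confusion([8, 9, 24, 25], [8, 9, 24, 25], ISS_CATEGORIES)
    assert np.array_equal(np.diag(mat), np.ones(4, dtype=int))
    labels = ISS_CATEGORIES.label_of([8, 9, 24, 25])
    assert list(labels) == ["mild", "moderate", "severe", "profound"]


def test_gcs_points_aggregation_uses_rts_map():
    labels = GCS_POINTS_CATEGORIES.label_of([3, 4, 6, 9, 13])
    assert list(labels) == ["0", "1", "2", "3", "4"]


def test_unmapped_value_errors():
    with pytest.raises(ValueError):
        ISS_CATEGORIES(np.array([0]))


# ---------------------------------------------------------------------------
# Youden metrics
# ---------------------------------------------------------------------------


def brute_force_youden(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    best = None
    for t in np.unique(scores):
        pred = scores >= t
        tpr = (pred & labels).sum() / labels.sum()
        tnr = (~pred & ~labels).sum() / (~labels).sum()
        j = tpr + tnr - 1
        if best is None or j > best[0] or (j == best[0] and t < best[1]):
            best = (j, t)
    return best


def test_youden_perfect_separation():
    rep = youden_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert rep.youden_j == pytest.approx(1.0)
    assert rep.tpr == rep.tnr == rep.ppv == rep.npv == rep.accuracy == rep.f1 == 1.0


def test_youden_matches_exhaustive_search(rng):
    for _ in range(30):
        n = int(rng.integers(8, 60))
        scores = rng.choice(np.linspace(0, 1, 9), n)
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            continue
        rep = youden_metrics(scores, labels)
        j, t = brute_force_youden(scores, labels)
        assert rep.youden_j == pytest.approx(j, abs=1e-12)
        assert rep.threshold == pytest.approx(t, abs=1e-12)


def test_youden_internal_consistency(rng):
    scores = rng.normal(size=300)
    labels = np.r_[np.ones(100, bool), np.zeros(200, bool)]
    scores[:100] += 1.0
    rep = youden_metrics(scores, labels)
    pred = scores >= rep.threshold
    assert rep.tpr == pytest.approx((pred & labels).sum() / 100)
    assert rep.tnr == pytest.approx((~pred & ~labels).sum() / 200)


def test_youden_null_scores_low_j(rng):
    scores = rng.normal(size=1000)
    labels = rng.random(1000) < 0.5
    rep = youden_metrics(scores, labels)
    assert rep.youden_j < 0.15


def test_youden_single_class_errors():
    with pytest.raises(ValueError):
        youden_metrics([0.1, 0.2], [0, 0])
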