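"""Evaluation statistics: hand-computed oracles, exhaustive bootstrap
enumeration, and invariants."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, f1_score

import neurofuse as nf
from neurofuse.metrics import (
    PredictionError, PredictionSet, bootstrap_ci,
    cohen_kappa, confusion, macro_f1, macro_metrics, paired_diff_ci,
)

HAND_CM = np.array([[1, 1, 0], [0, 2, 0], [0, 0, 2]])


def preds_from(y_true, y_pred):
    n = len(y_true)
    return PredictionSet(np.array([f"p{i}" for i in range(n)]),
                         np.array(y_true), np.array(y_pred))


# ---------------------------------------------------------------- confusion
def test_confusion_all_correct_is_diagonal():
    p = preds_from([0, 0, 1, 1, 1, 2, 2, 2, 2, 2],
                   [0, 0, 1, 1, 1, 2, 2, 2, 2, 2])
    np.testing.assert_array_equal(confusion(p), np.diag([2, 3, 5]))


def test_confusion_single_off_diagonal():
    cm = confusion(preds_from([1], [2]))
    assert cm[1, 2] == 1 and cm.sum() == 1


def test_confusion_matches_tally_loop():
    rng = np.random.default_rng(0)
    y_true = rng.integers(0, 3, 70)
    y_pred = rng.integers(0, 3, 70)
    cm = confusion(preds_from(y_true, y_pred))
    tally = np.zeros((3, 3), int)
    for t, p in zip(y_true, y_pred):
        tally[t, p] += 1
    np.testing.assert_array_equal(cm, tally)
    np.testing.assert_array_equal(cm.sum(axis=1), np.bincount(y_true, minlength=3))


def test_out_of_range_labels_rejected():
    with pytest.raises(PredictionError):
        preds_from([0, 3], [0, 0])
    with pytest.raises(PredictionError, match="unique"):
        PredictionSet(np.array(["a", "a"]), [0, 0], [0, 0])


# ------------------------------------------------------------ macro metrics
def test_perfect_predictions_score_100():
    m = macro_metrics(np.diag([2, 3, 5]))
    for key in ("ACC", "SEN", "SPE", "F1"):
        assert m[key] == pytest.approx(100.0)


def test_macro_metrics_hand_oracle():
    """One-vs-rest tables computed by hand for HAND_CM (n=6):
    SEN (1/2, 1, 1), SPE (1, 3/4, 1), F1 (2/3, 4/5, 1)."""
    m = macro_metrics(HAND_CM)
    assert m["ACC"] == pytest.approx(100 * 5 / 6, abs=1e-10)
    assert m["SEN"] == pytest.approx(100 * (0.5 + 1 + 1) / 3, abs=1e-10)
    assert m["SPE"] == pytest.approx(100 * (1 + 0.75 + 1) / 3, abs=1e-10)
    assert m["F1"] == pytest.approx(100 * (2 / 3 + 0.8 + 1) / 3, abs=1e-10)
    np.testing.assert_allclose(m["per_class"]["SEN"], [50, 100, 100])


def test_macro_metrics_match_sklearn_on_random_labels():
    rng = np.random.default_rng(3)
    y_true = rng.integers(0, 3, 70)
    y_pred = rng.integers(0, 3, 70)
    m = macro_metrics(confusion(preds_from(y_true, y_pred)))
    assert m["F1"] == pytest.approx(
        100 * f1_score(y_true, y_pred, average="macro"), abs=1e-9)


def test_empty_predicted_class_still_has_specificity():
    cm = np.array([[3, 0, 0], [2, 0, 0], [1, 0, 1]])  # class 1 never predicted
    m = macro_metrics(cm)
    assert np.isfinite(m["SPE"])
    assert m["per_class"]["SPE"][1] == pytest.approx(100.0)


def test_absent_true_class_is_flagged_and_excluded():
    cm = np.array([[2, 1, 0], [0, 0, 0], [0, 0, 3]])
    m = macro_metrics(cm)
    assert m["absent_classes"] == [1]
    assert m["SEN"] == pytest.approx(100 * (2 / 3 + 1) / 2)


def test_order_invariance():
    rng = np.random.default_rng(9)
    y_true = rng.integers(0, 3, 30)
    y_pred = rng.integers(0, 3, 30)
    perm = rng.permutation(30)
    a = macro_metrics(confusion(preds_from(y_true, y_pred)))
    b = macro_metrics(confusion(preds_from(y_true[perm], y_pred[perm])))
    assert a["ACC"] == b["ACC"] and a["F1"] == b["F1"]


# ----------------------------------------------------------------- kappa
def test_kappa_perfect_and_chance():
    assert cohen_kappa(np.diag([2, 3, 5])) == pytest.approx(100.0)
    assert cohen_kappa(np.array([[1, 1], [1, 1]])) == pytest.approx(0.0)


def test_kappa_hand_oracle():
    """po = 5/6, pe = (2*1 + 2*3 + 2*2)/36 = 1/3, kappa = 3/4."""
    assert cohen_kappa(HAND_CM) == pytest.approx(75.0, abs=1e-10)


def test_kappa_matches_sklearn():
    rng = np.random.default_rng(5)
    y_true = rng.integers(0, 3, 70)
    y_pred = rng.integers(0, 3, 70)
    assert cohen_kappa(confusion(preds_from(y_true, y_pred))) == pytest.approx(
        100 * cohen_kappa_score(y_true, y_pred), abs=1e-9)


def test_kappa_degenerate_table_is_zero():
    assert cohen_kappa(np.array([[4, 0], [0, 0]])) == 0.0


def test_kappa_invariant_to_class_relabeling():
    rng = np.random.default_rng(2)
    cm = rng.integers(0, 9, (3, 3))
    perm = [2, 0, 1]
    assert cohen_kappa(cm) == pytest.approx(
        cohen_kappa(cm[np.ix_(perm, perm)]), abs=1e-10)


# --------------------------------------------------------------- bootstrap
def test_all_correct_bootstrap_is_degenerate():
    p = preds_from([0, 1, 2, 0], [0, 1, 2, 0])
    s = bootstrap_ci(p, "macro_f1", B=200, seed=1)
    assert (s.point, s.ci_low, s.ci_high) == (100.0, 100.0, 100.0)


def enumeration_ci(preds, stat_fn):
    """Exact resampling distribution for n=4: all 4^4 = 256 index tuples."""
    n = len(preds)
    stats = [stat_fn(preds.subset(np.array(idx)))
             for idx in itertools.product(range(n), repeat=n)]
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(np.mean(stats)), float(lo), float(hi)


def test_bootstrap_matches_exhaustive_enumeration():
    p = preds_from([0, 1, 2, 2], [0, 1, 2, 1])  # one error
    exact_mean, exact_lo, exact_hi = enumeration_ci(p, macro_f1)
    s = bootstrap_ci(p, "macro_f1", B=20_000, seed=3)
    assert s.point == pytest.approx(exact_mean, abs=2.0)
    assert s.ci_low == pytest.approx(exact_lo, abs=2.0)
    assert s.ci_high == pytest.approx(exact_hi, abs=2.0)


def test_bootstrap_reproducible_and_bounded():
    rng = np.random.default_rng(8)
    p = preds_from(rng.integers(0, 3, 20), rng.integers(0, 3, 20))
    a = bootstrap_ci(p, "kappa", B=500, seed=4)
    b = bootstrap_ci(p, "kappa", B=500, seed=4)
    assert a.as_dict() == b.as_dict()
    stats = [nf.cohen_kappa(confusion(p.subset(idx))) for idx in
             np.random.default_rng(4).integers(0, 20, (500, 20))]
    assert min(stats) <= a.ci_low <= a.ci_high <= max(stats)


def test_paired_diff_identical_sets_is_zero():
    p = preds_from([0, 1, 2, 0], [0, 1, 1, 0])
    s = paired_diff_ci(p, p, "macro_f1", B=300, seed=0)
    assert (s.point, s.ci_low, s.ci_high) == (0.0, 0.0, 0.0)
    assert s.excludes_zero is False


def test_paired_diff_perfect_vs_always_wrong():
    a = preds_from([0, 1, 2, 0], [0, 1, 2, 0])
    b = preds_from([0, 1, 2, 0], [1, 2, 0, 1])
    s = paired_diff_ci(a, b, "macro_f1", B=300, seed=0)
    assert (s.point, s.ci_low, s.ci_high) == (100.0, 100.0, 100.0)
    assert s.excludes_zero is True


def test_paired_diff_matches_enumeration():
    a = preds_from([0, 1, 2, 2], [0, 1, 2, 2])
    b = preds_from([0, 1, 2, 2], [0, 1, 2, 1])
    n = 4
    diffs = [macro_f1(a.subset(np.array(idx))) - macro_f1(b.subset(np.array(idx)))
             for idx in itertools.product(range(n), repeat=n)]
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    s = paired_diff_ci(a, b, "macro_f1", B=20_000, seed=9)
    assert s.point == pytest.approx(np.mean(diffs), abs=2.0)
    assert s.ci_low == pytest.approx(lo, abs=2.0)
    assert s.ci_high == pytest.approx(hi, abs=2.0)


def test_paired_diff_requires_same_patients():
    a = preds_from([0, 1], [0, 1])
    b = PredictionSet(np.array(["x", "y"]), [0, 1], [0, 1])
    with pytest.raises(PredictionError, match="patient_ids"):
        paired_diff_ci(a, b)


def test_report_round_trips_through_csv(tmp_path):
    p = preds_from([0, 1, 2, 1, 0], [0, 1, 2, 2, 0])
    path = tmp_path / "preds.csv"
    p.to_csv(path)
    q = PredictionSet.from_csv(path)
    report = nf.evaluation_report(q, B=100, seed=0)
    assert report["n"] == 5
    assert report["metrics"]["ACC"] == pytest.approx(80.0)
    assert set(report["bootstrap"]) == {"macro_f1", "kappa"}
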