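"""Evaluation statistics over patient-level LOOCV predictions.

Point metrics: accuracy, one-vs-rest sensitivity/specificity/F1 per class
with unweighted macro averages, and Cohen's kappa — all in percent.
Uncertainty: percentile bootstrap (2.5th/97.5th percentiles of the statistic
over resamples of the patient records, drawn with replacement), and paired
bootstrap differences between two models' predictions on the same patients
(one index multiset applied to both sets per resample).

Macro averaging is used because the task prints single overall SEN/SPE/F1
values for a 3-class problem; classes absent from the truth of a (re)sample
are excluded from the macro mean and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class PredictionError(ValueError):
    pass


@dataclass
class PredictionSet:
    """(patient_id, true, predicted) records; one per patient under LOOCV."""

    patient_ids: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    n_classes: int = 3

    def __post_init__(self):
        self.patient_ids = np.asarray(self.patient_ids)
        self.y_true = np.asarray(self.y_true, dtype=int)
        self.y_pred = np.asarray(self.y_pred, dtype=int)
        if not (len(self.patient_ids) == len(self.y_true) == len(self.y_pred)):
            raise PredictionError("record arrays must have equal length")
        if len(np.unique(self.patient_ids)) != len(self.patient_ids):
            raise PredictionError("patient_ids must be unique")
        for arr, name in ((self.y_true, "true"), (self.y_pred, "pred")):
            if arr.size and (arr.min() < 0 or arr.max() >= self.n_classes):
                raise PredictionError(f"{name} labels outside 0..{self.n_classes - 1}")

    def __len__(self):
        return len(self.y_true)

    def subset(self, idx) -> "PredictionSet":
        # bootstrap resamples repeat patients; bypass the uniqueness check
        out = object.__new__(PredictionSet)
        out.patient_ids = self.patient_ids[idx]
        out.y_true = self.y_true[idx]
        out.y_pred = self.y_pred[idx]
        out.n_classes = self.n_classes
        return out

    @classmethod
    def from_csv(cls, path) -> "PredictionSet":
        df = pd.read_csv(path)
        need = {"patient_id", "true", "pred"}
        if not need <= set(df.columns):
            raise PredictionError(f"{path}: prediction CSV needs columns {sorted(need)}")
        return cls(df["patient_id"].to_numpy(), df["true"].to_numpy(),
                   df["pred"].to_numpy())

    def to_csv(self, path):
        pd.DataFrame({"patient_id": self.patient_ids, "true": self.y_true,
                      "pred": self.y_pred}).to_csv(path, index=False)


def confusion(preds: PredictionSet) -> np.ndarray:
    """K x K count matrix, rows = true class, columns = predicted class."""
    if len(preds) == 0:
        raise PredictionError("empty prediction set")
    K = preds.n_classes
    return np.bincount(preds.y_true * K + preds.y_pred,
                       minlength=K * K).reshape(K, K)


def macro_metrics(cm: np.ndarray) -> dict:
    """Accuracy plus per-class and macro one-vs-rest SEN/SPE/F1, in percent.

    Classes with no true members have undefined sensitivity/F1; they are
    excluded from the macro means and listed under ``absent_classes``.
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total <= 0:
        raise PredictionError("confusion matrix is empty")
    tp = np.diag(cm)
    row = cm.sum(axis=1)   # true-class counts
    col = cm.sum(axis=0)   # predicted-class counts
    fn = row - tp
    fp = col - tp
    tn = total - row - fp

    present = row > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        sen = np.where(present, tp / np.where(row > 0, row, 1), np.nan)
        # TN+FP = total - row; zero only when a single class holds all truth
        neg = tn + fp
        spe = np.where(neg > 0, tn / np.where(neg > 0, neg, 1), np.nan)
        denom = 2 * tp + fp + fn
        f1 = np.where(denom > 0, 2 * tp / np.where(denom > 0, denom, 1), 0.0)
    f1 = np.where(present, f1, np.nan)

    return {
        "ACC": 100.0 * tp.sum() / total,
        "SEN": 100.0 * np.nanmean(sen),
        "SPE": 100.0 * np.nanmean(spe),
        "F1": 100.0 * np.nanmean(f1),
        "per_class": {
            "SEN": (100.0 * sen).tolist(),
            "SPE": (100.0 * spe).tolist(),
            "F1": (100.0 * f1).tolist(),
        },
        "absent_classes": np.flatnonzero(~present).tolist(),
    }


def cohen_kappa(cm: np.ndarray) -> float:
    """Chance-corrected agreement (po - pe) / (1 - pe), in percent.

    Degenerate tables with pe = 1 (all marginal mass in one class) are
    defined as 0.
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total <= 0:
        raise PredictionError("confusion matrix is empty")
    po = np.trace(cm) / total
    pe = float(cm.sum(axis=1) @ cm.sum(axis=0)) / total ** 2
    if pe >= 1.0 - 1e-12:
        return 0.0
    return 100.0 * (po - pe) / (1.0 - pe)


def macro_f1(preds: PredictionSet) -> float:
    return macro_metrics(confusion(preds))["F1"]


_STATISTICS = {
    "macro_f1": macro_f1,
    "kappa": lambda p: cohen_kappa(confusion(p)),
}


@dataclass
class BootstrapSummary:
    statistic_name: str
    point: float          # mean over resamples, percent
    full_sample: float    # statistic on the un-resampled records, percent
    ci_low: float
    ci_high: float
    n_resamples: int
    seed: int
    excludes_zero: bool | None = None

    def as_dict(self):
        d = {k: getattr(self, k) for k in
             ("statistic_name", "point", "full_sample", "ci_low", "ci_high",
              "n_resamples", "seed")}
        if self.excludes_zero is not None:
            d["excludes_zero"] = self.excludes_zero
        return d


def _resolve_stat(statistic):
    if callable(statistic):
        return statistic, getattr(statistic, "__name__", "statistic")
    try:
        return _STATISTICS[statistic], statistic
    except KeyError:
        raise PredictionError(
            f"unknown statistic {statistic!r}; choose from {sorted(_STATISTICS)}")


def bootstrap_ci(preds: PredictionSet, statistic="macro_f1", B: int = 10_000,
                 seed: int = 0) -> BootstrapSummary:
    """Percentile bootstrap over patient records (size-n resamples with
    replacement; CI = 2.5th..97.5th percentile of the B statistics)."""
    if B < 1:
        raise PredictionError("B must be >= 1")
    fn, name = _resolve_stat(statistic)
    n = len(preds)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    stats = np.array([fn(preds.subset(idx[b])) for b in range(B)])
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return BootstrapSummary(name, float(stats.mean()), float(fn(preds)),
                            float(lo), float(hi), B, seed)


def paired_diff_ci(preds_a: PredictionSet, preds_b: PredictionSet,
                   statistic="macro_f1", B: int = 10_000,
                   seed: int = 0) -> BootstrapSummary:
    """Bootstrap CI of statistic(a) - statistic(b) with paired resampling:
    each resample applies one index multiset to both prediction sets."""
    if sorted(preds_a.patient_ids) != sorted(preds_b.patient_ids):
        raise PredictionError("paired bootstrap requires identical patient_ids")
    # align b to a's patient order
    order = {pid: i for i, pid in enumerate(preds_b.patient_ids)}
    b_idx = np.array([order[pid] for pid in preds_a.patient_ids])
    preds_b = preds_b.subset(b_idx)

    fn, name = _resolve_stat(statistic)
    n = len(preds_a)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    diffs = np.array([fn(preds_a.subset(idx[b])) - fn(preds_b.subset(idx[b]))
                      for b in range(B)])
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return BootstrapSummary(f"diff_{name}", float(diffs.mean()),
                            float(fn(preds_a) - fn(preds_b)),
                            float(lo), float(hi), B, seed,
                            excludes_zero=bool(lo > 0 or hi < 0))


def evaluation_report(preds: PredictionSet, B: int = 10_000, seed: int = 0,
                      against: PredictionSet | None = None) -> dict:
    """JSON-ready report: confusion matrix, point metrics, bootstrap CIs,
    and optionally the paired difference against a second model."""
    cm = confusion(preds)
    report = {
        "n": len(preds),
        "confusion_matrix": cm.tolist(),
        "metrics": macro_metrics(cm),
        "kappa": cohen_kappa(cm),
        "bootstrap": {
            name: bootstrap_ci(preds, name, B=B, seed=seed).as_dict()
            for name in ("macro_f1", "kappa")
        },
    }
    if against is not None:
        report["paired_diff"] = {
            name: paired_diff_ci(preds, against, name, B=B, seed=seed).as_dict()
            for name in ("macro_f1", "kappa")
        }
    return report
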