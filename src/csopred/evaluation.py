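"""Metrics, ROC/AUC/AUC01, k-fold cross-validation and model comparison.

Threshold convention: a site is called positive when ``score >= threshold``
(tie-inclusive).  Because the class ratio is unbalanced, threshold-dependent
metrics (ACC/SN/SP/MCC) are reported at an operating threshold anchored to a
target specificity — by default the threshold whose specificity is closest
to 0.80 on the fold being scored — while AUC and AUC01 are threshold-free.
AUC01 is the *unnormalised* area under the ROC restricted to a false-positive
rate below 0.1 (maximum attainable value 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests

from .dataio import Segment, segment_labels


class ConfusionCounts(NamedTuple):
    TP: int
    TN: int
    FP: int
    FN: int


def confusion_at_threshold(scores, labels, threshold: float) -> ConfusionCounts:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    pred = scores >= threshold
    return ConfusionCounts(
        TP=int(np.sum(pred & labels)),
        TN=int(np.sum(~pred & ~labels)),
        FP=int(np.sum(pred & ~labels)),
        FN=int(np.sum(~pred & labels)),
    )


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """ACC, SN, SP and MCC from a confusion matrix.

    ACC = (TP+TN)/(TP+FP+TN+FN); SN = TP/(TP+FN); SP = TN/(TN+FP);
    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)), with the
    convention MCC = 0 when the denominator vanishes.
    """
    tp, tn, fp, fn = (float(v) for v in c)
    n = tp + tn + fp + fn
    acc = (tp + tn) / n if n else 0.0
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = (tp * tn - fn * fp) / np.sqrt(denom) if denom > 0 else 0.0
    return {"ACC": acc, "SN": sn, "SP": sp, "MCC": mcc}


def roc_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points and trapezoidal AUC (equals the concordant-pair
    probability with ties counted half)."""
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


def auc01(scores, labels, normalized: bool = False) -> float:
    """Area under the ROC restricted to FPR in [0, 0.1].

    Unnormalised by default (maximum 0.1); ``normalized=True`` divides
    by 0.1.
    """
    fpr, tpr, _ = roc_curve(labels, scores)
    cut = 0.1
    keep = fpr <= cut
    f = fpr[keep]
    t = tpr[keep]
    if f[-1] < cut:
        t_at_cut = float(np.interp(cut, fpr, tpr))
        f = np.append(f, cut)
        t = np.append(t, t_at_cut)
    area = float(np.trapezoid(t, f))
    return area / cut if normalized else area


def threshold_at_specificity(scores, labels, target_sp: float) -> float:
    """Smallest threshold whose specificity is >= ``target_sp``.

    Specificity at threshold t is the fraction of negatives scoring below t
    (the >= rule calls ties positive).  When even the largest observed score
    leaves some negatives called positive, a threshold just above the maximum
    score is returned (specificity 1).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    neg = scores[~labels]
    candidates = np.unique(scores)
    for t in candidates:
        if np.mean(neg < t) >= target_sp:
            return float(t)
    return float(np.nextafter(candidates[-1], np.inf))


def threshold_closest_specificity(scores, labels, target_sp: float = 0.80) -> float:
    """Threshold whose achieved specificity is closest to ``target_sp``."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    neg = scores[~labels]
    candidates = np.unique(scores)
    sps = np.array([np.mean(neg < t) for t in candidates])
    return float(candidates[int(np.argmin(np.abs(sps - target_sp)))])


SPECIFICITY_LEVELS = (0.80, 0.85, 0.90)

METRIC_COLUMNS = ("ACC", "SN", "SP", "MCC", "AUC", "AUC01")


@dataclass
class EvalReport:
    per_fold: pd.DataFrame  # fold, ACC, SN, SP, MCC, AUC, AUC01, threshold
    roc_curves: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    oof_scores: np.ndarray | None = None
    oof_labels: np.ndarray | None = None
    thresholds: dict[float, float] = field(default_factory=dict)

    @property
    def summary(self) -> pd.DataFrame:
        cols = [c for c in METRIC_COLUMNS if c in self.per_fold.columns]
        return self.per_fold[cols].agg(["mean", "std"])

    def write_tsv(self, per_fold_path, summary_path=None) -> None:
        self.per_fold.to_csv(per_fold_path, sep="\t", index=False)
        if summary_path is not None:
            self.summary.to_csv(summary_path, sep="\t")


def evaluate_scores(scores, labels, sp_target: float = 0.80) -> dict[str, float]:
    """All six metrics for one scored set, thresholded at the specificity
    anchor."""
    thr = threshold_closest_specificity(scores, labels, sp_target)
    out = metrics(confusion_at_threshold(scores, labels, thr))
    _, _, auc = roc_auc(scores, labels)
    out["AUC"] = auc
    out["AUC01"] = auc01(scores, labels)
    out["threshold"] = thr
    return out


def kfold_cv(
    spec,
    cv_groups: list[list[Segment]],
    seed: int = 0,
    sp_target: float = 0.80,
    aaindex_properties=None,
) -> EvalReport:
    """Cross-validate a model spec over pre-built groups of segments.

    Each group serves once as the validation fold; PSSM matrices (and any
    normalisation inside the model) are fitted on the training folds only.
    Returns per-fold metrics, ROC curves, pooled out-of-fold scores, and
    specificity-calibrated thresholds at 80/85/90% computed on the pooled
    out-of-fold predictions.
    """
    from . import models as M
    from .encoders import build_pssm

    rows = []
    curves = []
    oof_scores: list[np.ndarray] = []
    oof_labels: list[np.ndarray] = []
    for fold, val_group in enumerate(cv_groups):
        train_segments = [s for g, grp in enumerate(cv_groups) if g != fold for s in grp]
        artifacts = {}
        if spec.encoding in ("pssm", "pssm_image"):
            artifacts["pssm"] = build_pssm(
                [s for s in train_segments if s.is_positive],
                [s for s in train_segments if not s.is_positive],
            )
        if aaindex_properties is not None:
            artifacts["aaindex"] = aaindex_properties
        X_train = M.encode_for(spec, train_segments, artifacts)
        X_val = M.encode_for(spec, val_group, artifacts)
        y_train = segment_labels(train_segments)
        y_val = segment_labels(val_group)
        model = M.train(spec, X_train, y_train, seed=seed + fold)
        scores = M.predict_scores(model, X_val)
        row = evaluate_scores(scores, y_val, sp_target)
        row["fold"] = fold
        rows.append(row)
        fpr, tpr, _ = roc_auc(scores, y_val)
        curves.append((fpr, tpr))
        oof_scores.append(scores)
        oof_labels.append(y_val)
    per_fold = pd.DataFrame(rows)[["fold", *METRIC_COLUMNS, "threshold"]]
    pooled_scores = np.concatenate(oof_scores)
    pooled_labels = np.concatenate(oof_labels)
    thresholds = {
        level: threshold_at_specificity(pooled_scores, pooled_labels, level)
        for level in SPECIFICITY_LEVELS
    }
    return EvalReport(per_fold, curves, pooled_scores, pooled_labels, thresholds)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def compare_models(
    report_a: EvalReport,
    report_b: EvalReport,
    metric_names=METRIC_COLUMNS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired t-tests on per-fold metric values between two CV reports, with
    Benjamini-Hochberg adjustment across the compared metrics."""
    rows = []
    for name in metric_names:
        a = report_a.per_fold[name].to_numpy(dtype=float)
        b = report_b.per_fold[name].to_numpy(dtype=float)
        if len(a) != len(b):
            raise ValueError("reports have different numbers of folds")
        diff = a - b
        if np.allclose(diff, diff[0]):
            # zero-variance differences: identical folds -> no evidence;
            # a constant non-zero shift -> overwhelming evidence
            if np.isclose(diff[0], 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = float(np.sign(diff[0]) * np.inf), 0.0
        else:
            t, p = stats.ttest_rel(a, b)
        rows.append({"metric": name, "mean_diff": float(np.mean(diff)),
                     "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].fillna(1.0))
    out["significant"] = out["p_adj"] < alpha
    return out
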