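"""ROC/AUC evaluation, optimal-epoch selection and risk reporting.

Per-epoch accuracy, sensitivity, specificity and AUC on each data split;
selection of the "optimal" epoch per fold; arithmetic mean-of-folds
aggregation; vertical ROC-curve averaging on a fixed FPR grid; and ranked
per-case rupture-risk reports.  Positive class = ruptured throughout.

The ROC construction sweeps thresholds over the unique scores with tied
scores stepping simultaneously, so the trapezoidal AUC equals the
Mann-Whitney pair-counting statistic (ties counted 1/2) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: metrics of the summary table, in reporting order
METRIC_COLUMNS = ("val_auc", "accuracy", "sensitivity", "specificity",
                  "test_auc")


@dataclass
class EpochMetrics:
    """Threshold metrics plus AUC for one split at one epoch."""

    split: str
    epoch: int
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float = 0.5


@dataclass
class ROCCurve:
    """Operating points (FPR, TPR nondecreasing) and trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class RiskReport:
    """Softmax rupture-risk score of one case."""

    sample_id: str
    risk_score: float
    label: int | None = None
    cohort: str = ""
    alert: bool = False


def _check_two_class(labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.intp)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to form an ROC curve")
    return labels


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve by threshold sweep and its trapezoidal AUC.

    Thresholds run over the unique scores in decreasing order; tied scores
    step the curve simultaneously (diagonal segments), which makes the
    trapezoidal area identical to Mann-Whitney pair counting with ties
    worth one half.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = _check_two_class(labels)
    if len(scores) != len(labels):
        raise ValueError("scores and labels differ in length")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # group tied scores
    distinct = np.concatenate([[True], np.diff(s) != 0])
    group = np.cumsum(distinct) - 1
    n_groups = group[-1] + 1
    tp = np.bincount(group, weights=y, minlength=n_groups).cumsum()
    fp = np.bincount(group, weights=1 - y, minlength=n_groups).cumsum()
    P, N = y.sum(), (1 - y).sum()
    tpr = np.concatenate([[0.0], tp / P])
    fpr = np.concatenate([[0.0], fp / N])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, auc=auc)


def confusion_metrics(scores, labels, threshold: float = 0.5,
                      split: str = "internal_val",
                      epoch: int = 0) -> EpochMetrics:
    """Accuracy/sensitivity/specificity at ``score >= threshold`` = ruptured."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.intp)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    acc = (tp + tn) / len(labels)
    try:
        auc = roc_auc(scores, labels).auc
    except ValueError:
        auc = np.nan
    return EpochMetrics(split=split, epoch=epoch, auc=auc, accuracy=acc,
                        sensitivity=sens, specificity=spec,
                        threshold=threshold)


def confusion_table(scores, labels, threshold: float = 0.5) -> pd.DataFrame:
    """2x2 confusion matrix (rows = truth, columns = prediction)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.intp)
    pred = (scores >= threshold).astype(int)
    tab = pd.crosstab(pd.Series(labels, name="truth"),
                      pd.Series(pred, name="predicted"))
    return tab.reindex(index=[0, 1], columns=[0, 1], fill_value=0)


compute_epoch_metrics = confusion_metrics


def select_optimal_epoch(per_epoch: list, policy: str = "guarded",
                         gap_max: float = 0.15) -> int:
    """Pick the reporting epoch of a fold from its per-epoch records.

    ``per_epoch`` is a list of dicts mapping split name to
    :class:`EpochMetrics`.  The default ``"guarded"`` policy maximizes the
    internal-validation AUC subject to the train/validation AUC gap staying
    below ``gap_max`` (overfitting guard) and never consults the external
    set, so no external information leaks into model selection.  The
    ``"min_of_three"`` policy instead maximizes the minimum AUC across
    train, internal and external splits.  Ties go to the earliest epoch.
    """
    if not per_epoch:
        raise ValueError("no epochs recorded")
    if policy == "guarded":
        best, best_auc = None, -np.inf
        for i, rec in enumerate(per_epoch):
            gap = rec["train"].auc - rec["internal_val"].auc
            if gap > gap_max:
                continue
            if rec["internal_val"].auc > best_auc:
                best, best_auc = i, rec["internal_val"].auc
        if best is not None:
            return best
        # every epoch overfits past the gap; fall back to best validation
        return int(np.argmax([r["internal_val"].auc for r in per_epoch]))
    if policy == "min_of_three":
        vals = []
        for rec in per_epoch:
            vals.append(min(m.auc for m in rec.values()))
        return int(np.argmax(vals))
    raise ValueError(f"unknown policy {policy!r}")


def aggregate_folds(per_fold: list) -> dict:
    """Unweighted arithmetic mean of per-fold metric rows.

    ``per_fold`` holds one mapping of metric name -> value per fold.
    Returns full-precision means plus 2-decimal rounded values under
    ``<name>_2dp`` keys, matching the convention of printed summary tables.
    """
    if not per_fold:
        raise ValueError("need at least one fold")
    keys = per_fold[0].keys()
    out = {}
    for k in keys:
        m = float(np.mean([row[k] for row in per_fold]))
        out[k] = m
        out[f"{k}_2dp"] = round(m, 2)
    return out


def mean_roc(curves: list, n_grid: int = 101) -> ROCCurve:
    """Vertical average of ROC curves on a fixed FPR grid."""
    if not curves:
        raise ValueError("need at least one curve")
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = [np.interp(grid, c.fpr, c.tpr) for c in curves]
    tpr = np.mean(tprs, axis=0)
    return ROCCurve(fpr=grid, tpr=tpr, auc=float(np.trapezoid(tpr, grid)))


def plot_roc(curves, path, labels=None, title="Mean ROC"):
    """Write an ROC plot (individual curves plus their vertical mean)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for i, c in enumerate(curves):
        name = labels[i] if labels else f"fold {i + 1}"
        ax.plot(c.fpr, c.tpr, alpha=0.5, lw=1,
                label=f"{name} (AUC {c.auc:.2f})")
    if len(curves) > 1:
        m = mean_roc(list(curves))
        ax.plot(m.fpr, m.tpr, "k-", lw=2, label=f"mean (AUC {m.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate (1 - specificity)")
    ax.set_ylabel("true positive rate (sensitivity)")
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def summary_table(fold_rows: list, model_name: str = "cut1") -> pd.DataFrame:
    """Per-fold metric rows plus the arithmetic-mean Average row."""
    df = pd.DataFrame(fold_rows)
    df.insert(0, "pattern", [f"Fold {i + 1}" for i in range(len(fold_rows))])
    mean = {c: df[c].mean() for c in df.columns if c != "pattern"}
    mean["pattern"] = "Average"
    df = pd.concat([df, pd.DataFrame([mean])], ignore_index=True)
    df.insert(0, "model", model_name)
    return df


def fold_summary(results, policy: str = "guarded",
                 threshold: float = 0.5) -> list:
    """Metric row per fold at its optimal epoch (val metrics + test AUC)."""
    rows = []
    for res in results:
        i = select_optimal_epoch(res.epoch_records, policy=policy)
        rec = res.epoch_records[i]
        row = {
            "val_auc": rec["internal_val"].auc,
            "accuracy": rec["internal_val"].accuracy,
            "sensitivity": rec["internal_val"].sensitivity,
            "specificity": rec["internal_val"].specificity,
        }
        if "external_test" in rec:
            row["test_auc"] = rec["external_test"].auc
        row["epoch"] = i
        rows.append(row)
    return rows


def score_cases(classifier, samples: dict, alert_level: float = 0.5,
                net_config=None) -> list:
    """Rank cases by softmax rupture-risk score.

    ``samples`` maps id -> LabeledSample (or PointCloud).  Per-case failures
    (e.g. cloud too small for the network) are reported in the returned
    entry and do not stop the run.
    """
    from .net import build_plan, softmax

    cfg = net_config if net_config is not None else classifier.config
    reports = []
    for sid, sample in samples.items():
        cloud = getattr(sample, "cloud", sample)
        label = getattr(sample, "label", None)
        cohort = getattr(sample, "cohort", "")
        try:
            plan = build_plan(cloud.coords, cfg)
            logits = classifier.forward([plan])[0]
            score = float(softmax(logits)[1])
        except Exception as exc:
            reports.append(RiskReport(sample_id=str(sid),
                                      risk_score=float("nan"),
                                      label=label, cohort=cohort))
            import warnings

            warnings.warn(f"case {sid}: scoring failed ({exc}); continuing")
            continue
        reports.append(RiskReport(sample_id=str(sid), risk_score=score,
                                  label=label, cohort=cohort,
                                  alert=score >= alert_level))
    reports.sort(key=lambda r: (-r.risk_score if np.isfinite(r.risk_score)
                                else np.inf))
    return reports


def risk_table(reports: list) -> pd.DataFrame:
    """Ranked DataFrame of risk reports (positive class = ruptured)."""
    return pd.DataFrame([{"rank": i + 1, "id": r.sample_id,
                          "risk_score": r.risk_score, "label": r.label,
                          "cohort": r.cohort, "alert": r.alert}
                         for i, r in enumerate(reports)])
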