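"""Classification metric panel: confusion counts, sensitivity/specificity,
predictive values, likelihood ratios, ROC/AUC, confidence intervals, and
group descriptive statistics.

CI methods (the standard choices for this panel): Wilson score intervals for
proportions, DeLong variance for the AUC, and the log-method for likelihood
ratios.  All intervals are clipped to their valid ranges.  Undefined values
(zero denominators) are reported as NaN rather than raised.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.proportion import proportion_confint

from gaitfall.errors import DataError

from gaitfall.classification import TrainedModel, predict_risk


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise DataError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    """Cross-tabulate binary labels vs predictions (positive class = 1)."""
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    if labels.shape != predictions.shape:
        raise DataError("labels and predictions must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((labels == 1) & (predictions == 1))),
        fn=int(np.sum((labels == 1) & (predictions == 0))),
        fp=int(np.sum((labels == 0) & (predictions == 1))),
        tn=int(np.sum((labels == 0) & (predictions == 0))),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def rates(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, PPV, NPV, PLR, NLR.  Undefined
    denominators yield NaN."""
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    return {
        "accuracy": _ratio(c.tp + c.tn, c.total),
        "sensitivity": sens,
        "specificity": spec,
        "ppv": _ratio(c.tp, c.tp + c.fp),
        "npv": _ratio(c.tn, c.tn + c.fn),
        "plr": _ratio(sens, 1.0 - spec) if not math.isnan(sens + spec) else float("nan"),
        "nlr": _ratio(1.0 - sens, spec) if not math.isnan(sens + spec) else float("nan"),
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> dict:
    """ROC curve points and AUC (Mann-Whitney: the probability a random
    positive outscores a random negative, ties counted one half)."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise DataError("both classes required to compute a ROC curve")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return {"auc": float(roc_auc_score(labels, scores)),
            "fpr": fpr.tolist(), "tpr": tpr.tolist(),
            "thresholds": thresholds.tolist()}


# ---------------------------------------------------------------------------
# confidence intervals
# ---------------------------------------------------------------------------


def _delong_auc_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance of the empirical AUC (midrank structural components)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # V10[i]: fraction of negatives outscored by positive i (ties half)
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def wilson_interval(successes: int, total: int, level: float = 0.95
                    ) -> tuple[float, float]:
    if total == 0:
        return (float("nan"), float("nan"))
    lo, hi = proportion_confint(successes, total, alpha=1 - level,
                                method="wilson")
    return float(lo), float(hi)


def _lr_interval(value: float, terms: list[tuple[int, int]], level: float
                 ) -> tuple[float, float]:
    """Log-method CI for a likelihood ratio: terms are (count, group total)
    contributing 1/count - 1/total each to var(ln LR)."""
    if math.isnan(value) or value <= 0:
        return (float("nan"), float("nan"))
    if any(count == 0 for count, _ in terms):
        return (float("nan"), float("nan"))
    var = sum(1.0 / count - 1.0 / total for count, total in terms)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(var)
    return (value * math.exp(-half), value * math.exp(half))


def confidence_intervals(c: ConfusionCounts, scores: np.ndarray,
                         labels: np.ndarray, level: float = 0.95
                         ) -> dict[str, tuple[float, float]]:
    """95% (by default) intervals for every panel metric."""
    r = rates(c)
    z = stats.norm.ppf(0.5 + level / 2.0)
    auc = roc_auc_score(labels, scores)
    se = math.sqrt(_delong_auc_variance(np.asarray(scores, dtype=float),
                                        np.asarray(labels).astype(int)))
    out = {
        "accuracy": wilson_interval(c.tp + c.tn, c.total, level),
        "sensitivity": wilson_interval(c.tp, c.tp + c.fn, level),
        "specificity": wilson_interval(c.tn, c.tn + c.fp, level),
        "ppv": wilson_interval(c.tp, c.tp + c.fp, level),
        "npv": wilson_interval(c.tn, c.tn + c.fn, level),
        "plr": _lr_interval(r["plr"], [(c.tp, c.tp + c.fn), (c.fp, c.fp + c.tn)],
                            level),
        "nlr": _lr_interval(r["nlr"], [(c.fn, c.tp + c.fn), (c.tn, c.fp + c.tn)],
                            level),
        "auc": (max(0.0, auc - z * se), min(1.0, auc + z * se)),
    }
    return out


# ---------------------------------------------------------------------------
# group descriptives
# ---------------------------------------------------------------------------


def group_descriptives(cohort: pd.DataFrame, variables: list[str],
                       label_column: str = "risk_label") -> pd.DataFrame:
    """Per-variable mean +/- SD by risk group, Welch two-sided t-test p, and
    Shapiro-Wilk normality p (skipped with a flag for groups of < 3)."""
    high = cohort[cohort[label_column] == 1]
    low = cohort[cohort[label_column] == 0]
    if len(high) == 0 or len(low) == 0:
        raise DataError("both risk groups must be non-empty")
    rows = []
    for var in variables:
        a, b = high[var].to_numpy(float), low[var].to_numpy(float)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        pooled = cohort[var].to_numpy(float)
        shapiro_p = (float(stats.shapiro(pooled).pvalue)
                     if len(pooled) >= 3 else float("nan"))
        rows.append({
            "variable": var,
            "high_mean": a.mean(), "high_sd": a.std(ddof=1),
            "low_mean": b.mean(), "low_sd": b.std(ddof=1),
            "t_statistic": float(t), "p_value": float(p),
            "significant": bool(p < 0.05),
            "shapiro_p": shapiro_p,
            "shapiro_skipped": len(pooled) < 3,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------


def full_report(model: TrainedModel, test: pd.DataFrame,
                label_column: str = "risk_label",
                descriptive_variables: list[str] | None = None) -> dict:
    """Assemble the complete metric panel for one speed's model on the
    holdout set: confusion counts, rates with CIs, ROC/AUC, and the top-10
    importance ranking.  JSON-serializable and deterministic given the seed."""
    from gaitfall.classification import feature_importance_ranking

    labels = test[label_column].to_numpy().astype(int)
    scores, predicted = predict_risk(model, test[list(model.feature_names)])
    c = confusion(labels, predicted)
    roc = roc_auc(scores, labels)
    r = rates(c)
    cis = confidence_intervals(c, scores, labels)
    report = {
        "n_test": int(c.total),
        "confusion": asdict(c),
        "metrics": {**r, "auc": roc["auc"]},
        "confidence_intervals": {k: list(v) for k, v in cis.items()},
        "roc": {"fpr": roc["fpr"], "tpr": roc["tpr"]},
        "importance_top10": feature_importance_ranking(model, top_k=10),
        "config": {
            "n_trees": model.config.n_trees,
            "learning_rate": model.config.learning_rate,
            "max_depth": model.config.max_depth,
            "threshold": model.config.threshold,
            "seed": model.config.seed,
        },
    }
    if descriptive_variables:
        report["descriptives"] = group_descriptives(
            test, descriptive_variables, label_column).to_dict(orient="records")
    return report


def report_to_json(report: dict) -> str:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not serializable: {type(o)}")
    return json.dumps(report, indent=2, default=default)
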