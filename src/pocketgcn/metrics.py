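"""Evaluation statistics and per-target report aggregation.

Classification: AUC (rank-based, mid-rank ties), TPR, precision,
accuracy, MCC, F1, with positive/negative counts.  Regression: RMSE,
MSE, Pearson, Spearman, concordance index, and Prmsd (RMSE divided by
the mean pKa of the evaluated set, a relative-error summary).

Report aggregation mirrors the published table layout: the
classification ALL row is computed on the pooled score/label vectors
(not a mean of per-target metrics), while the regression Average row is
the unweighted mean of per-target metrics; count columns are exact sums
in both.

Metrics with a zero denominator are reported as 0.0 and listed in the
row's ``flags`` so table output stays usable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

CLASSIFICATION_COLUMNS = (
    "name", "auc", "tpr", "precision", "accuracy", "mcc", "f1",
    "pos_num", "neg_num",
)
REGRESSION_COLUMNS = (
    "name", "rmse", "mse", "pearson", "spearman", "prmsd", "total_num",
)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = (s >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y == 1))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
    )


def _safe_div(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def classification_metrics(
    scores, labels, threshold: float = 0.5, name: str = ""
) -> dict:
    """One report row.  AUC is the Mann-Whitney rank statistic (mid-rank
    ties); with a single-class label vector it is reported as 0.0 and
    flagged ``auc_undefined`` while the threshold metrics still compute.
    """
    y = np.asarray(labels, dtype=int)
    flags: list[str] = []
    c = confusion_counts(scores, labels, threshold)
    if y.min() == y.max():
        auc = 0.0
        flags.append("auc_undefined")
    else:
        auc = float(roc_auc_score(y, np.asarray(scores, dtype=float)))
    mcc_den = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    tpr = _safe_div(c.tp, c.tp + c.fn, flags, "tpr_undefined")
    precision = _safe_div(c.tp, c.tp + c.fp, flags, "precision_undefined")
    f1 = _safe_div(2 * c.tp, 2 * c.tp + c.fp + c.fn, flags, "f1_undefined")
    return {
        "name": name,
        "auc": auc,
        "tpr": tpr,
        "precision": precision,
        "accuracy": _safe_div(c.tp + c.tn, c.n, flags, "accuracy_undefined"),
        "mcc": _safe_div(c.tp * c.tn - c.fp * c.fn, mcc_den, flags, "mcc_undefined"),
        "f1": f1,
        "pos_num": int(c.tp + c.fn),
        "neg_num": int(c.tn + c.fp),
        "flags": flags,
    }


def concordance_index(pred, truth) -> float:
    """Fraction of comparable pairs predicted in the right order.

    Pairs with tied truth are not comparable; ties in prediction count
    one half.  Vectorized over one index of the pair loop.
    """
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    concordant = 0.0
    comparable = 0
    n = len(p)
    for i in range(n):
        diff_t = t[i] - t[:i]
        diff_p = p[i] - p[:i]
        mask = diff_t != 0
        comparable += int(mask.sum())
        agree = np.sign(diff_t[mask]) == np.sign(diff_p[mask])
        ties = diff_p[mask] == 0
        concordant += float(np.sum(agree & ~ties)) + 0.5 * float(np.sum(ties))
    if comparable == 0:
        raise ValueError("no comparable pairs (constant truth vector)")
    return concordant / comparable


def regression_metrics(pred, truth, name: str = "") -> dict:
    """One regression report row; a constant prediction vector yields
    Pearson/Spearman 0.0 with a flag instead of a NaN."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.size < 2:
        raise ValueError("pred and truth must be equal-length vectors of size >= 2")
    flags: list[str] = []
    mse = float(np.mean((p - t) ** 2))
    rmse = math.sqrt(mse)
    if np.ptp(p) == 0 or np.ptp(t) == 0:
        pearson = spearman = 0.0
        flags.append("correlation_undefined")
    else:
        pearson = float(stats.pearsonr(p, t).statistic)
        spearman = float(stats.spearmanr(p, t).statistic)
    try:
        ci = concordance_index(p, t)
    except ValueError:
        ci = 0.0
        flags.append("ci_undefined")
    return {
        "name": name,
        "rmse": rmse,
        "mse": mse,
        "pearson": pearson,
        "spearman": spearman,
        "ci": ci,
        "prmsd": prmsd(rmse, t) if np.all(np.isfinite(t)) and t.mean() > 0 else 0.0,
        "total_num": int(p.size),
        "flags": flags,
    }


def prmsd(rmse: float, pka_values) -> float:
    """Relative error: RMSE divided by the mean pKa of the evaluated set."""
    pka = np.asarray(pka_values, dtype=float)
    if pka.size == 0:
        raise ValueError("empty pKa list")
    mean = float(pka.mean())
    if mean <= 0:
        raise ValueError("mean pKa must be positive")
    return rmse / mean


def binarize_docking(score_kcal: float, cutoff_kcal: float = -6.0) -> int:
    """Docking score to binary call: <= cutoff (more negative, stronger
    predicted binding) -> 1, otherwise 0.  Common cutoffs: -5, -6, -7."""
    if not math.isfinite(score_kcal):
        raise ValueError("docking score must be finite")
    return 1 if score_kcal <= cutoff_kcal else 0


def aggregate_classification_report(
    rows: list[dict],
    pooled_scores=None,
    pooled_labels=None,
    threshold: float = 0.5,
) -> list[dict]:
    """Append the ALL row: metrics recomputed on the pooled vectors when
    they are supplied (never a mean of rows), counts summed exactly."""
    if not rows:
        raise ValueError("no rows to aggregate")
    required = {"pos_num", "neg_num"}
    for row in rows:
        if not required <= set(row):
            raise ValueError(f"row missing count columns: {row.get('name', '?')}")
    if pooled_scores is not None:
        all_row = classification_metrics(
            pooled_scores, pooled_labels, threshold=threshold, name="ALL"
        )
    else:
        all_row = {"name": "ALL", "flags": ["metrics_require_pooled_scores"]}
    all_row["pos_num"] = int(sum(r["pos_num"] for r in rows))
    all_row["neg_num"] = int(sum(r["neg_num"] for r in rows))
    return rows + [all_row]


def aggregate_regression_report(rows: list[dict]) -> list[dict]:
    """Append the Average row: unweighted mean of per-target metrics,
    summed total_num."""
    if not rows:
        raise ValueError("no rows to aggregate")
    metric_cols = [c for c in ("rmse", "mse", "pearson", "spearman", "ci", "prmsd") if all(c in r for r in rows)]
    avg = {"name": "Average"}
    for c in metric_cols:
        avg[c] = float(np.mean([r[c] for r in rows]))
    avg["total_num"] = int(sum(r["total_num"] for r in rows))
    return rows + [avg]


def report_to_tsv(rows: list[dict], columns) -> str:
    def fmt(v):
        if isinstance(v, float):
            return f"{v:.2f}"
        return str(v)

    lines = ["\t".join(columns)]
    for r in rows:
        lines.append("\t".join(fmt(r.get(c, "")) for c in columns))
    return "\n".join(lines) + "\n"
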