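"""Multiclass evaluation: confusion matrix, one-vs-rest per-family metrics,
macro aggregates, and the Wilcoxon signed-rank comparison of two runs.

Per-family counts come from the one-vs-rest reduction of a multiclass
confusion matrix (TP+FP+FN+TN = n for every family). Two metric modes exist:

* ``standard`` (default): Sen = TP/(TP+FN), Spec = TN/(TN+FP).
* ``paper``: Sen = TP/(TP+FP), Spec = TN/(TP+FN), reproducing a published
  formula set verbatim for fidelity audits. In this mode specificity is not
  bounded by 1 whenever TN > TP+FN; such values are flagged, never clipped.

Both modes share Acc = (TP+TN)/n and F = 2TP/(2TP+FP+FN); any 0/0 ratio is
defined as 0 so absent families do not poison macro means. The macro F-score
is the unweighted arithmetic mean of per-family F scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

__all__ = [
    "confusion_matrix",
    "per_class_metrics",
    "MetricsTable",
    "wilcoxon_signed_rank",
    "significance_stars",
    "compare_metric_tables",
]

METRIC_COLUMNS = ("accuracy", "sensitivity", "specificity", "f_score")


def confusion_matrix(
    y_true: Sequence, y_pred: Sequence, families: Sequence[str] | None = None
) -> pd.DataFrame:
    """C[i, j] = count of true family i predicted as family j.

    Families absent from the data get zero rows/columns; labels outside the
    supplied family list are an error.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred differ in length")
    if families is None:
        families = sorted(set(y_true) | set(y_pred))
    else:
        families = list(families)
        unknown = (set(y_true) | set(y_pred)) - set(families)
        if unknown:
            raise ValueError(f"labels not in the family list: {sorted(unknown)!r}")
    C = _sk_confusion_matrix(y_true, y_pred, labels=families)
    return pd.DataFrame(C, index=families, columns=families)


def _safe_div(num: float, den: float) -> float:
    return 0.0 if den == 0 else num / den


@dataclass
class MetricsTable:
    """Per-family counts and metrics plus macro aggregates."""

    table: pd.DataFrame  # index: families; columns: TP FP FN TN + metrics
    macro_f: float
    macro_recall: float
    macro_precision: float
    mode: str
    out_of_range: list[str]  # families where a paper-mode metric exceeded 1

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        df.to_csv(path, sep="\t", index_label="family", float_format="%.6f")


def per_class_metrics(cm: pd.DataFrame, mode: str = "standard") -> MetricsTable:
    """One-vs-rest TP/FP/FN/TN and the four metrics for every family."""
    if mode not in ("standard", "paper"):
        raise ValueError(f"mode must be 'standard' or 'paper', got {mode!r}")
    C = cm.to_numpy()
    if C.size == 0:
        raise ValueError("empty confusion matrix")
    n = C.sum()
    tp = np.diag(C).astype(float)
    fp = C.sum(axis=0) - tp
    fn = C.sum(axis=1) - tp
    tn = n - tp - fp - fn

    rows = []
    out_of_range: list[str] = []
    recalls, precisions = [], []
    for i, fam in enumerate(cm.index):
        acc = _safe_div(tp[i] + tn[i], n)
        f = _safe_div(2 * tp[i], 2 * tp[i] + fp[i] + fn[i])
        if mode == "paper":
            sen = _safe_div(tp[i], tp[i] + fp[i])
            spec = _safe_div(tn[i], tp[i] + fn[i])
            if sen > 1.0 or spec > 1.0:
                out_of_range.append(fam)
        else:
            sen = _safe_div(tp[i], tp[i] + fn[i])
            spec = _safe_div(tn[i], tn[i] + fp[i])
        recalls.append(_safe_div(tp[i], tp[i] + fn[i]))
        precisions.append(_safe_div(tp[i], tp[i] + fp[i]))
        rows.append(
            {
                "TP": int(tp[i]), "FP": int(fp[i]), "FN": int(fn[i]), "TN": int(tn[i]),
                "accuracy": acc, "sensitivity": sen, "specificity": spec, "f_score": f,
            }
        )
    if out_of_range:
        warnings.warn(
            "paper-mode specificity/sensitivity exceeded 1 for families "
            f"{out_of_range!r} (the printed formula is unbounded); values kept as computed"
        )
    table = pd.DataFrame(rows, index=list(cm.index))
    return MetricsTable(
        table=table,
        macro_f=float(table["f_score"].mean()),
        macro_recall=float(np.mean(recalls)),
        macro_precision=float(np.mean(precisions)),
        mode=mode,
        out_of_range=out_of_range,
    )


def _exact_wplus_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Count of sign assignments per value of 2*W+ (subset-sum DP)."""
    total = int(doubled_ranks.sum())
    dp = np.zeros(total + 1)
    dp[0] = 1.0
    for r in doubled_ranks:
        new = dp.copy()
        new[r:] += dp[: total + 1 - r]
        dp = new
    return dp


def wilcoxon_signed_rank(
    a: Sequence[float], b: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test of a vs b.

    Zero differences are dropped; tied absolute differences get midranks. The
    null distribution of W+ is computed exactly (dynamic programming over all
    2^n sign assignments) for n <= 25 and by a tie-corrected normal
    approximation above. Returns (T, p) with T = min(W+, W-). If every
    difference is zero the test is degenerate: (0, 1) with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors differ in length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; Wilcoxon test is degenerate")
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    stat = min(w_plus, w_minus)

    if n <= 25:
        r2 = np.rint(2 * ranks).astype(int)
        dist = _exact_wplus_distribution(r2)
        total = 2.0**n
        w2 = int(round(2 * w_plus))
        p_le = dist[: w2 + 1].sum() / total
        p_ge = dist[w2:].sum() / total
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        from scipy.stats import norm

        z = (w_plus - mu) / np.sqrt(var)
        p_le = float(norm.cdf(z))
        p_ge = float(norm.sf(z))

    if alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_le, p_ge))
    elif alternative == "greater":  # a tends to exceed b
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return stat, float(p)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_metric_tables(a: MetricsTable, b: MetricsTable) -> dict:
    """Per-metric Wilcoxon signed-rank comparison of two per-family tables."""
    if list(a.table.index) != list(b.table.index):
        raise ValueError("metric tables cover different family lists")
    out = {}
    for metric in METRIC_COLUMNS:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = wilcoxon_signed_rank(
                a.table[metric].to_numpy(), b.table[metric].to_numpy()
            )
        out[metric] = {"statistic": round(stat, 6), "p": round(p, 6), "stars": significance_stars(p)}
    return out
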