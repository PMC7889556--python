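"""Cohort-level diagnostics: ROC, cutoff selection, diagnostic tables.

Functional indices predict PHLF with *low* values, so the positive
test direction is "score <= cutoff" (inclusive) by default.  The AUC
is the Mann-Whitney probability that a random positive scores more
test-positive than a random negative (ties counted half); its 95 %
confidence interval uses the DeLong covariance estimator.  Cutoffs are
chosen on the midpoint grid between adjacent distinct scores by
maximising sensitivity + specificity, breaking ties by the larger
positive likelihood ratio, then the smaller negative likelihood
ratio, then the smaller cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "DiagnosticRow",
    "classify_by_cutoff",
    "confusion_counts",
    "diagnostics",
    "roc",
    "select_cutoff",
    "mann_whitney",
    "pearson_r",
    "median_iqr",
    "build_table5",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class DiagnosticRow:
    """One diagnostic-accuracy table row for an endpoint x index pair."""

    endpoint: str
    index: str
    cutoff: float
    auc: float
    auc_ci95: tuple[float, float]
    se: float
    sp: float
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float


def classify_by_cutoff(
    scores: np.ndarray, cutoff: float, low_is_positive: bool = True
) -> np.ndarray:
    """Predicted labels from a score threshold.

    Positive iff ``score <= cutoff`` when ``low_is_positive`` (the
    clinical convention for function scores: low function predicts
    failure), else ``score >= cutoff``.
    """
    scores = np.asarray(scores, dtype=float)
    if np.any(~np.isfinite(scores)):
        raise ValueError("scores contain NaN or infinite values")
    return scores <= cutoff if low_is_positive else scores >= cutoff


def confusion_counts(predicted: np.ndarray, labels: np.ndarray) -> ConfusionCounts:
    predicted = np.asarray(predicted, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    if predicted.shape != labels.shape:
        raise ValueError("predicted and true labels differ in length")
    return ConfusionCounts(
        tp=int(np.sum(predicted & labels)),
        fp=int(np.sum(predicted & ~labels)),
        tn=int(np.sum(~predicted & ~labels)),
        fn=int(np.sum(~predicted & labels)),
    )


def diagnostics(counts: ConfusionCounts) -> dict[str, float]:
    """Se/Sp/PPV/NPV and likelihood ratios from a confusion matrix.

    Percentages are full precision; LR+ is ``se/(100-sp)`` (infinite
    when specificity is 100 %), LR- is ``(100-se)/sp``.
    """
    if counts.tp + counts.fn == 0:
        raise ValueError("no positive cases: sensitivity undefined")
    if counts.tn + counts.fp == 0:
        raise ValueError("no negative cases: specificity undefined")
    se = 100.0 * counts.tp / (counts.tp + counts.fn)
    sp = 100.0 * counts.tn / (counts.tn + counts.fp)
    ppv = 100.0 * counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else float("nan")
    npv = 100.0 * counts.tn / (counts.tn + counts.fn) if counts.tn + counts.fn else float("nan")
    lr_pos = se / (100.0 - sp) if sp < 100.0 else float("inf")
    lr_neg = (100.0 - se) / sp if sp > 0.0 else float("inf")
    return {"se": se, "sp": sp, "ppv": ppv, "npv": npv, "lr_pos": lr_pos, "lr_neg": lr_neg}


def _positivity_scores(scores: np.ndarray, low_is_positive: bool) -> np.ndarray:
    # Higher transformed score = more test-positive.
    return -scores if low_is_positive else scores


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_auc_var(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from positive/negative scores."""
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    r_all = _midrank(all_scores)
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n  # structural components for positives
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(auc), s10 / m + s01 / n


def roc(
    scores: np.ndarray,
    labels: np.ndarray,
    low_is_positive: bool = True,
    alpha: float = 0.05,
) -> dict:
    """ROC curve, AUC and DeLong 95 % confidence interval.

    Returns a dict with ``fpr``, ``tpr``, ``thresholds`` (on the
    original score scale), ``auc`` and ``auc_ci95``.  The AUC equals
    the Mann-Whitney probability U/(n_pos * n_neg) with ties counted
    half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if np.any(~np.isfinite(scores)):
        raise ValueError("scores contain NaN or infinite values")
    if labels.all() or not labels.any():
        raise ValueError("ROC analysis requires both classes")
    s = _positivity_scores(scores, low_is_positive)
    pos, neg = s[labels], s[~labels]
    auc, var = _delong_auc_var(pos, neg)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, s)
    thresholds = -thr if low_is_positive else thr
    return {"fpr": fpr, "tpr": tpr, "thresholds": thresholds, "auc": auc, "auc_ci95": ci}


def select_cutoff(
    scores: np.ndarray, labels: np.ndarray, low_is_positive: bool = True
) -> float:
    """Optimal cutoff by the largest sensitivity + specificity sum.

    Candidates are midpoints between adjacent distinct observed scores
    plus one candidate below the minimum and one above the maximum.
    Ties are broken by the larger LR+, then the smaller LR-, then the
    smaller cutoff, making the choice deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if np.any(~np.isfinite(scores)):
        raise ValueError("scores contain NaN or infinite values")
    if labels.all() or not labels.any():
        raise ValueError("cutoff selection requires both classes")
    distinct = np.unique(scores)
    if len(distinct) < 2:
        raise ValueError("all scores identical: no discriminating cutoff exists")
    span = distinct[-1] - distinct[0]
    candidates = np.concatenate(
        (
            [distinct[0] - 0.5 * span],
            (distinct[:-1] + distinct[1:]) / 2.0,
            [distinct[-1] + 0.5 * span],
        )
    )
    best: tuple | None = None
    best_cutoff = None
    for c in candidates:
        counts = confusion_counts(classify_by_cutoff(scores, c, low_is_positive), labels)
        d = diagnostics(counts)
        lr_pos = d["lr_pos"] if math.isfinite(d["lr_pos"]) else float("inf")
        lr_neg = d["lr_neg"] if math.isfinite(d["lr_neg"]) else float("inf")
        key = (d["se"] + d["sp"], lr_pos, -lr_neg, -c)
        if best is None or key > best:
            best = key
            best_cutoff = float(c)
    return best_cutoff


def mann_whitney(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U (group_a vs group_b) with two-sided asymptotic p.

    The statistic satisfies the AUC identity ``U = AUC * n_a * n_b``
    when group_a holds the positive-class scores.
    """
    group_a = np.asarray(group_a, dtype=float)
    group_b = np.asarray(group_b, dtype=float)
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    res = stats.mannwhitneyu(group_a, group_b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation coefficient with two-sided p (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def median_iqr(values: np.ndarray) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linearly interpolated quartiles."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q1), float(q3)


_ENDPOINT_POSITIVE = {
    "50-50": lambda df: df["fifty_fifty"].astype(bool),
    "ISGLS-B": lambda df: df["isgls_grade"] == "B",
    "ISGLS-A/B": lambda df: df["isgls_grade"].isin(["A", "B"]),
}


def build_table5(
    cohort: pd.DataFrame,
    endpoints: tuple[str, ...] = ("50-50", "ISGLS-B", "ISGLS-A/B"),
    indices: tuple[str, ...] = ("flr_f", "hiba_i"),
    low_is_positive: bool = True,
) -> pd.DataFrame:
    """Full diagnostic-accuracy table: one row per endpoint x index.

    For each endpoint (50-50 criteria; ISGLS grade B with grades none
    and A as negatives; ISGLS grade A or B) and each functional index,
    the cutoff is selected by `select_cutoff` and the confusion-matrix
    metrics and DeLong AUC interval are computed at that cutoff.
    Endpoints with an empty class raise.
    """
    needed = set(indices) | {"isgls_grade"}
    if "50-50" in endpoints:
        needed.add("fifty_fifty")
    missing = sorted(needed - set(cohort.columns))
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    rows = []
    for endpoint in endpoints:
        if endpoint not in _ENDPOINT_POSITIVE:
            raise ValueError(f"unknown endpoint {endpoint!r}")
        labels = _ENDPOINT_POSITIVE[endpoint](cohort).to_numpy()
        for index in indices:
            scores = cohort[index].to_numpy(dtype=float)
            cutoff = select_cutoff(scores, labels, low_is_positive)
            counts = confusion_counts(
                classify_by_cutoff(scores, cutoff, low_is_positive), labels
            )
            d = diagnostics(counts)
            r = roc(scores, labels, low_is_positive)
            rows.append(
                DiagnosticRow(
                    endpoint=endpoint,
                    index=index,
                    cutoff=cutoff,
                    auc=r["auc"],
                    auc_ci95=r["auc_ci95"],
                    se=d["se"],
                    sp=d["sp"],
                    ppv=d["ppv"],
                    npv=d["npv"],
                    lr_pos=d["lr_pos"],
                    lr_neg=d["lr_neg"],
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])
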