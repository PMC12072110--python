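"""Group-comparison statistics and ROC threshold discovery.

Implements the evaluation suite used on per-stage MFI data: summary
statistics (median/IQR, mean/SD), Shapiro-Wilk normality screening,
Kruskal-Wallis global tests with Dunn's pairwise z-tests under a
multiplicative Bonferroni adjustment, and ROC analysis with optimal
thresholds chosen by the Youden index (J = sensitivity + specificity
- 1), reported with full confusion-matrix metrics in the "positive if
value > threshold" direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin

from ._utils import round_half_up


@dataclass(frozen=True)
class SummaryStats:
    median: float
    iqr: float
    mean: float
    sd: float
    n: int


def summarize(values) -> SummaryStats:
    """Median/IQR (linear-interpolation quantiles) and mean/SD (n-1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("at least one value is required")
    q1, q3 = np.percentile(x, [25, 75])
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return SummaryStats(float(np.median(x)), float(q3 - q1),
                        float(np.mean(x)), sd, int(x.size))


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p for 3 <= n <= 5000."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn-Bonferroni
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    """Global Kruskal-Wallis result plus a symmetric pairwise p table."""

    h: float
    p: float
    pairwise: pd.DataFrame | None
    labels: tuple[str, ...]


def _as_groups(groups) -> tuple[tuple[str, ...], list[np.ndarray]]:
    if isinstance(groups, Mapping):
        labels = tuple(groups)
        arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        labels = tuple(f"group_{i}" for i in range(len(arrays)))
    if len(arrays) < 2:
        raise ValueError("at least two groups are required")
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group needs at least one value")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("at least three values are required in total")
    return labels, arrays


def kruskal_wallis(groups) -> GroupComparison:
    """Tie-corrected H with a chi-square (k-1 df) p-value."""
    labels, arrays = _as_groups(groups)
    if np.ptp(np.concatenate(arrays)) == 0:  # all observations identical
        return GroupComparison(0.0, 1.0, None, labels)
    h, p = sps.kruskal(*arrays)
    return GroupComparison(float(h), float(p), None, labels)


def pairwise_bonferroni(groups) -> pd.DataFrame:
    """Dunn's z-tests on pooled ranks, Bonferroni-multiplied, clipped at 1."""
    labels, arrays = _as_groups(groups)
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start:start + a.size].mean())
        sizes.append(a.size)
        start += a.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n_total - 1))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(labels) * (len(labels) - 1) // 2
    table = pd.DataFrame(np.ones((len(labels), len(labels))),
                         index=labels, columns=labels)
    for i, j in combinations(range(len(labels)), 2):
        se = math.sqrt(variance_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:  # all observations identical
            p_adj = 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p_adj = min(1.0, 2.0 * sps.norm.sf(abs(z)) * n_pairs)
        table.iloc[i, j] = table.iloc[j, i] = p_adj
    return table


def compare_groups(groups) -> GroupComparison:
    """Kruskal-Wallis followed by Dunn-Bonferroni pairwise comparisons."""
    global_part = kruskal_wallis(groups)
    return GroupComparison(global_part.h, global_part.p,
                           pairwise_bonferroni(groups), global_part.labels)


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCResult:
    """AUC with the full ROC polyline and the raw group values."""

    auc: float
    points: np.ndarray  # ordered (1 - specificity, sensitivity) pairs
    n_pos: int
    n_neg: int
    pos_values: np.ndarray
    neg_values: np.ndarray


def roc_auc(pos_values, neg_values) -> ROCResult:
    """AUC as the normalized Mann-Whitney U statistic (ties count 1/2)."""
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size < 1 or neg.size < 1:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([pos, neg])
    ranks = sps.rankdata(pooled)
    u = ranks[:pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    auc = u / (pos.size * neg.size)
    # curve points at every distinct cutpoint, "positive if value > t"
    cuts = np.unique(pooled)[::-1]
    sens = np.array([(pos > t).mean() for t in cuts])
    fpr = np.array([(neg > t).mean() for t in cuts])
    points = np.vstack([[0.0, 0.0], np.column_stack([fpr, sens]), [1.0, 1.0]])
    return ROCResult(float(auc), points, pos.size, neg.size, pos, neg)


@dataclass(frozen=True)
class ThresholdMetrics:
    """Confusion counts and rate metrics for one decision threshold.

    Rates are percentages at full precision; ``report`` renders them
    rounded half-up to one decimal.  PPV/NPV are ``None`` when their
    denominator is empty.
    """

    threshold: float
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be >= 0")
        if self.tp + self.fn < 1 or self.tn + self.fp < 1:
            raise ValueError("both classes need at least one observation")

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        denom = self.tp + self.fp
        return 100.0 * self.tp / denom if denom else None

    @property
    def npv(self) -> float | None:
        denom = self.tn + self.fn
        return 100.0 * self.tn / denom if denom else None

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fn + self.tn + self.fp
        return 100.0 * (self.tp + self.tn) / total

    @property
    def youden(self) -> float:
        return (self.sensitivity + self.specificity) / 100.0 - 1.0

    def report(self) -> dict:
        rounded = lambda v: None if v is None else round_half_up(v, 1)
        return {
            "threshold": self.threshold, "TP": self.tp, "FN": self.fn,
            "TN": self.tn, "FP": self.fp,
            "sensitivity": rounded(self.sensitivity),
            "specificity": rounded(self.specificity),
            "PPV": rounded(self.ppv), "NPV": rounded(self.npv),
            "accuracy": rounded(self.accuracy),
        }


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> ThresholdMetrics:
    """Rate metrics from explicit confusion counts (no threshold attached)."""
    return ThresholdMetrics(float("nan"), tp, fn, tn, fp)


def _counts_at(threshold: float, pos: np.ndarray, neg: np.ndarray):
    tp = int((pos > threshold).sum())
    fp = int((neg > threshold).sum())
    return tp, pos.size - tp, neg.size - fp, fp


def best_threshold(roc: ROCResult) -> ThresholdMetrics:
    """Threshold maximizing Youden J over midpoints of distinct values.

    Ties in J are broken toward higher specificity, then toward the
    larger threshold; candidates outside the observed range (classify
    all one way) are included.
    """
    pooled = np.unique(np.concatenate([roc.pos_values, roc.neg_values]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    candidates = np.concatenate([[pooled[0] - 1.0], mids, [pooled[-1] + 1.0]])
    best: ThresholdMetrics | None = None
    for t in candidates:
        m = ThresholdMetrics(float(t), *_counts_at(t, roc.pos_values,
                                                   roc.neg_values))
        if (best is None
                or m.youden > best.youden + 1e-12
                or (abs(m.youden - best.youden) <= 1e-12
                    and (m.specificity, m.threshold)
                    > (best.specificity, best.threshold))):
            best = m
    return best


class YoudenThreshold(BaseEstimator, ClassifierMixin):
    """Single-marker threshold classifier fitted by the Youden index.

    ``fit(X, y)`` takes one feature column and binary labels, runs the
    ROC analysis and stores ``threshold_``, ``auc_`` and ``metrics_``;
    ``predict`` applies "positive if value > threshold_".
    """

    def fit(self, X, y) -> "YoudenThreshold":
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("YoudenThreshold expects exactly one feature")
            x = x[:, 0]
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("two classes are required")
        self.classes_ = classes
        roc = roc_auc(x[y == classes[1]], x[y == classes[0]])
        self.auc_ = roc.auc
        self.metrics_ = best_threshold(roc)
        self.threshold_ = self.metrics_.threshold
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        return np.where(x > self.threshold_, self.classes_[1], self.classes_[0])


def roc_table(cohorts: Mapping[str, Mapping[str, Sequence[float]]],
              blast_values: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """AUC matrix: rows = markers, columns = blast-vs-stage comparisons."""
    rows = {}
    for marker, pos in blast_values.items():
        rows[marker] = {
            stage: roc_auc(pos, neg_by_marker[marker]).auc
            for stage, neg_by_marker in cohorts.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index")
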