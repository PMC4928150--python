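"""Performance statistics, majority baseline, forest-size sweep and
information-gain feature ranking.

The five statistics are the standard confusion-matrix summaries:

    Accuracy  = (TP + TN) / (TP + TN + FP + FN)
    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)
    F-score   = 2 / (Precision^-1 + Recall^-1)
    MCC       = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with pathogenic ("disease") variants as the positive class.  When a factor
under the MCC root is zero (e.g. a constant predictor) the coefficient is
reported as 0 and flagged degenerate rather than raising.

Feature relevance is ranked by information gain: the reduction in label
entropy (bits) from conditioning on one feature.  Numeric features are
discretized first — by default with Fayyad–Irani supervised MDL binning,
optionally with equal-frequency 10-bin cuts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import ValidationError

__all__ = [
    "MetricsReport",
    "FeatureRanking",
    "compute_metrics",
    "majority_baseline",
    "information_gain",
    "rank_features",
    "sweep_forest_size",
]


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the five derived statistics."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f_score: float
    mcc: float
    degenerate: bool = False

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f_score": self.f_score, "mcc": self.mcc,
            "degenerate": self.degenerate,
        }

    def __str__(self) -> str:
        return (
            f"n={self.n} TP={self.tp} FP={self.fp} TN={self.tn} FN={self.fn} | "
            f"Acc={self.accuracy:.4f} Prec={self.precision:.4f} "
            f"Rec={self.recall:.4f} F={self.f_score:.4f} MCC={self.mcc:.4f}"
        )


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> MetricsReport:
    """Evaluate the five statistics from raw confusion counts."""
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValidationError(f"negative count {name}={v}")
    total = tp + fp + tn + fn
    if total < 1:
        raise ValidationError("at least one evaluated instance required")

    degenerate = False
    accuracy = (tp + tn) / total
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, degenerate = 0.0, True
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, degenerate = 0.0, True
    if precision + recall > 0:
        f_score = 2 * precision * recall / (precision + recall)
    else:
        f_score, degenerate = 0.0, True
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom > 0:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    else:
        mcc, degenerate = 0.0, True
    return MetricsReport(tp, fp, tn, fn, accuracy, precision, recall, f_score, mcc, degenerate)


def majority_baseline(disease: int, neutral: int) -> float:
    """Accuracy of the naive classifier that always predicts the larger class."""
    if disease < 0 or neutral < 0:
        raise ValidationError("counts must be non-negative")
    if disease + neutral < 1:
        raise ValidationError("at least one variant required")
    return max(disease, neutral) / (disease + neutral)


# ---------------------------------------------------------------------------
# Information gain


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a count vector."""
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _label_counts(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return np.array([(labels == c).sum() for c in classes])


def _mdl_cut_points(values: np.ndarray, labels: np.ndarray) -> list[float]:
    """Fayyad–Irani recursive entropy minimization with the MDL stop rule."""
    order = np.argsort(values, kind="mergesort")
    v, y = values[order], labels[order]
    classes = np.unique(labels)
    cuts: list[float] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2:
            return
        seg_v, seg_y = v[lo:hi], y[lo:hi]
        base_counts = _label_counts(seg_y, classes)
        base_ent = _entropy(base_counts)
        if base_ent == 0.0:
            return

        best_gain, best_i, best_stats = 0.0, None, None
        left = np.zeros(len(classes))
        for i in range(n - 1):
            left[np.searchsorted(classes, seg_y[i])] += 1
            if seg_v[i] == seg_v[i + 1]:
                continue  # can only cut between distinct values
            right = base_counts - left
            ent = (i + 1) / n * _entropy(left) + (n - i - 1) / n * _entropy(right)
            gain = base_ent - ent
            if gain > best_gain:
                best_gain, best_i = gain, i
                best_stats = (left.copy(), right.copy())
        if best_i is None:
            return

        left, right = best_stats
        k = int((base_counts > 0).sum())
        k1 = int((left > 0).sum())
        k2 = int((right > 0).sum())
        delta = math.log2(3**k - 2) - (
            k * base_ent - k1 * _entropy(left) - k2 * _entropy(right)
        )
        threshold = (math.log2(n - 1) + delta) / n
        if best_gain <= threshold:
            return
        cuts.append((seg_v[best_i] + seg_v[best_i + 1]) / 2.0)
        recurse(lo, lo + best_i + 1)
        recurse(lo + best_i + 1, hi)

    recurse(0, len(v))
    return sorted(cuts)


def _discretize(values: np.ndarray, labels: np.ndarray, discretization: str) -> np.ndarray:
    """Map numeric values to integer bin codes; NaN becomes its own bin."""
    missing = np.isnan(values)
    codes = np.full(len(values), -1, dtype=int)
    present = ~missing
    if present.any():
        vp = values[present]
        if len(np.unique(vp)) <= 2:
            # already binary: use the two values as categories outright
            codes[present] = np.searchsorted(np.unique(vp), vp)
            return codes
        if discretization == "mdl":
            cuts = _mdl_cut_points(vp, labels[present])
        elif discretization == "bins":
            qs = np.quantile(vp, np.linspace(0, 1, 11)[1:-1])
            cuts = sorted(set(qs.tolist()))
        else:
            raise ValidationError(f"unknown discretization {discretization!r}")
        codes[present] = np.searchsorted(cuts, vp, side="right")
    return codes


def information_gain(
    feature_values, labels, discretization: str = "mdl"
) -> float:
    """Reduction of label entropy (bits) from conditioning on one feature.

    Numeric features are discretized per ``discretization`` ("mdl" for
    supervised Fayyad–Irani binning, "bins" for equal-frequency deciles);
    categorical features are used as-is.  Missing numeric values form their
    own bin.  The result is floored at 0 against rounding.
    """
    values = np.asarray(feature_values)
    y = np.asarray([str(v) for v in labels])
    if len(values) != len(y):
        raise ValidationError("feature and label lengths differ")
    if len(y) < 2:
        raise ValidationError("information gain requires at least 2 instances")

    if values.dtype.kind in "fiub":
        codes = _discretize(values.astype(float), y, discretization)
    else:
        _, codes = np.unique(values.astype(str), return_inverse=True)

    classes = np.unique(y)
    h_label = _entropy(_label_counts(y, classes))
    n = len(y)
    cond = 0.0
    for code in np.unique(codes):
        mask = codes == code
        cond += mask.sum() / n * _entropy(_label_counts(y[mask], classes))
    return max(0.0, h_label - cond)


@dataclass
class FeatureRanking:
    """Features sorted by non-increasing information gain."""

    ranking: list[tuple[str, float]]
    discretization: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranking, columns=["feature", "information_gain"])

    def rank_of(self, feature: str) -> int:
        """1-based rank of ``feature``."""
        for i, (name, _) in enumerate(self.ranking, start=1):
            if name == feature:
                return i
        raise KeyError(feature)

    def top(self, n: int) -> list[str]:
        return [name for name, _ in self.ranking[:n]]


def rank_features(
    matrix: pd.DataFrame, labels, discretization: str = "mdl"
) -> FeatureRanking:
    """Information gain per semantic feature column, sorted descending.

    Ties are broken by the column order of ``matrix``, which for featurizer
    output is the fixed documented feature order.
    """
    y = list(labels)
    gains = []
    for pos, col in enumerate(matrix.columns):
        gain = information_gain(matrix.iloc[:, pos].to_numpy(), y, discretization)
        gains.append((col, gain, pos))
    gains.sort(key=lambda t: (-t[1], t[2]))
    return FeatureRanking([(name, gain) for name, gain, _ in gains], discretization)


def sweep_forest_size(
    data,
    ann,
    graph,
    scales=None,
    sizes: list[int] | None = None,
    k: int = 10,
    seed: int = 0,
    **cv_kwargs,
) -> pd.DataFrame:
    """One grouped cross-validation per forest size, identical folds throughout.

    Returns the comparison table ``n_trees accuracy precision recall
    f_score mcc`` used to pick the forest size.
    """
    from .model import cross_validate  # local import to avoid a cycle
    from .scales import DEFAULT_SCALES

    if sizes is None:
        sizes = list(range(4, 31))
    if not sizes or any(s < 1 for s in sizes):
        raise ValidationError("sizes must be a non-empty list of integers >= 1")
    scales = scales or DEFAULT_SCALES
    rows = []
    for size in sizes:
        result = cross_validate(
            data, ann, graph, scales, k=k, n_trees=size, seed=seed, **cv_kwargs
        )
        r = result.report
        rows.append(
            {
                "n_trees": size,
                "accuracy": r.accuracy,
                "precision": r.precision,
                "recall": r.recall,
                "f_score": r.f_score,
                "mcc": r.mcc,
            }
        )
    return pd.DataFrame(rows)
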