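"""Feature scaling, class weighting, and evaluation statistics.

Binding affinity (IC50, nM) and TAP transport efficiency enter the
classifier after min-max scaling, y = (x - x_min) / (x_max - x_min), with
the extrema taken from the training split only and persisted with the
model; inference-time values outside the training range are clamped to
[0, 1].  IC50 spans five orders of magnitude, so its default scaler applies
a log10 transform before the min-max step (the canonical treatment of nM
affinities); TAP scores are scaled on their raw scale.

Class imbalance between non-immunogenic and immunogenic records is handled
by weighting the loss per class with

    w_c = (1 / S_c) * (T / 2)

where S_c is the class count and T the total number of training instances.
The weighted class masses then satisfy w_pos*S_pos + w_neg*S_neg = T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class DegenerateRangeError(ValueError):
    """All inputs identical: min-max scaling undefined."""


class EmptyClassError(ValueError):
    """A class has zero instances; weighting undefined."""


@dataclass(frozen=True)
class NormalizationConstants:
    """Training-split extrema for one feature, with an optional pre-transform.

    ``transform`` is ``"identity"`` or ``"log10"``; the extrema are stored on
    the transformed scale.
    """

    x_min: float
    x_max: float
    transform: str = "identity"

    def __post_init__(self) -> None:
        if not self.x_max > self.x_min:
            raise DegenerateRangeError(
                f"x_max ({self.x_max}) must exceed x_min ({self.x_min})"
            )
        if self.transform not in ("identity", "log10"):
            raise ValueError(f"unknown transform {self.transform!r}")


def _pretransform(x, transform: str):
    if transform == "log10":
        return np.log10(np.maximum(np.asarray(x, dtype=float), 1e-12))
    return np.asarray(x, dtype=float)


def fit_minmax(values, transform: str = "identity") -> NormalizationConstants:
    """Fit min-max constants on (optionally log10-transformed) training values."""
    arr = _pretransform(values, transform)
    if arr.size < 2 or np.ptp(arr) == 0:
        raise DegenerateRangeError(
            "min-max scaling needs at least two distinct values"
        )
    return NormalizationConstants(float(arr.min()), float(arr.max()), transform)


def apply_minmax(x, c: NormalizationConstants):
    """Scale ``x`` to [0, 1] via (x - x_min)/(x_max - x_min), clamped.

    Clamping handles inference-time values outside the training range.
    Accepts scalars or arrays; monotone non-decreasing in ``x``.
    """
    arr = _pretransform(x, c.transform)
    y = np.clip((arr - c.x_min) / (c.x_max - c.x_min), 0.0, 1.0)
    return float(y) if np.isscalar(x) else y


@dataclass(frozen=True)
class ClassWeights:
    """Per-class loss weights balancing positive/negative instance counts."""

    w_pos: float
    w_neg: float
    s_pos: int
    s_neg: int

    @property
    def total(self) -> int:
        return self.s_pos + self.s_neg

    def per_sample(self, labels) -> np.ndarray:
        """Weight vector aligned with a 0/1 label array."""
        labels = np.asarray(labels)
        return np.where(labels == 1, self.w_pos, self.w_neg)


def class_weights(s_pos: int, s_neg: int) -> ClassWeights:
    """Compute w_c = (1/S_c) * (T/2) for the positive and negative classes."""
    if s_pos <= 0 or s_neg <= 0:
        raise EmptyClassError(
            f"both classes must be non-empty (got {s_pos} positive, {s_neg} negative)"
        )
    total = s_pos + s_neg
    return ClassWeights(
        w_pos=(1.0 / s_pos) * (total / 2.0),
        w_neg=(1.0 / s_neg) * (total / 2.0),
        s_pos=s_pos,
        s_neg=s_neg,
    )


def binary_metrics(predicted_positive, actual) -> tuple[float, float | None, float]:
    """Accuracy, precision and recall from boolean predictions and labels.

    Precision is ``None`` when there are no predicted positives; recall is 0
    when there are actual positives but no true positives, and ``None`` when
    there are no actual positives at all.
    """
    pred = np.asarray(predicted_positive, dtype=bool)
    act = np.asarray(actual, dtype=bool)
    if pred.shape != act.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {act.shape}")
    if pred.size == 0:
        raise ValueError("empty inputs")
    tp = int(np.sum(pred & act))
    accuracy = float(np.mean(pred == act))
    precision = tp / int(pred.sum()) if pred.any() else None
    recall = tp / int(act.sum()) if act.any() else None
    return accuracy, precision, recall


#: Conventional thresholds for calling a peptide an HLA binder.
IC50_BINDING_THRESHOLD_NM = 500.0
PERCENTILE_BINDING_THRESHOLD = 1.0


def threshold_binding(ic50: float, percentile: float) -> bool:
    """Binder call: IC50 < 500 nM AND rank percentile < 1% (both strict)."""
    return ic50 < IC50_BINDING_THRESHOLD_NM and percentile < PERCENTILE_BINDING_THRESHOLD


def significance_stars(p_value: float) -> str:
    """Conventional star annotation for a p-value (``ns`` at p >= 0.05)."""
    if p_value < 1e-4:
        return "****"
    if p_value < 1e-3:
        return "***"
    if p_value < 1e-2:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


def compare_distributions(group_a, group_b) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum comparison of two feature distributions.

    Returns ``(statistic, p_value, stars)``.  The rank-sum test is used
    because features like IC50 are heavily skewed; the annotation string
    follows the usual convention (**** for p < 1e-4, ns for p >= 0.05).
    """
    a, b = np.asarray(group_a, dtype=float), np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue), significance_stars(res.pvalue)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson correlation coefficient R with its two-sided p-value."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    if x.size < 3:
        raise ValueError("Pearson correlation needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateRangeError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) identity."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise EmptyClassError("AUROC needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
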