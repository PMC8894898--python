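"""Inter-hemispheric asymmetry biomarker.

The asymmetry index AI(lh, rh) = (lh - rh) / (lh + rh) is zero for perfect
symmetry and bounded in [-1, +1]; being a ratio it is scale-invariant and
needs no covariate correction — the contralateral side is the internal
reference. Normative limits are the healthy-control mean AI plus/minus 2 or
3 sample SDs (centered on the HC mean, which is slightly negative for
hippocampal volume: the right hippocampus tends to be marginally larger).
Scans outside the limits are flagged to a side according to the metric's
direction of change under disease: volume *decreases* on the affected side,
surface-to-volume ratio *increases*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .io import UNILATERAL_HS_GROUPS

__all__ = [
    "AsymmetryLimits",
    "ClassificationOutcome",
    "METRIC_DIRECTIONS",
    "WITHIN_NORM",
    "LEFT_ABNORMAL",
    "RIGHT_ABNORMAL",
    "asymmetry_index",
    "fit_normative_limits",
    "classify_by_asymmetry",
    "binary_metrics",
    "roc_auc",
]

WITHIN_NORM = "within-norm"
LEFT_ABNORMAL = "left-abnormal"
RIGHT_ABNORMAL = "right-abnormal"

#: Direction the metric moves on the *affected* side in hippocampal
#: sclerosis. "decrease": affected-left pushes AI down (volume loss);
#: "increase": affected-left pushes AI up (surface-to-volume ratio).
METRIC_DIRECTIONS: Dict[str, str] = {
    "volume": "decrease",
    "mesh_volume": "decrease",
    "voxel_volume": "decrease",
    "surface_to_volume_ratio": "increase",
}


def asymmetry_index(lh: float, rh: float) -> float:
    """AI = (lh - rh) / (lh + rh); raises if lh + rh == 0."""
    lh = float(lh)
    rh = float(rh)
    total = lh + rh
    if total == 0:
        raise ZeroDivisionError("asymmetry index undefined for lh + rh == 0")
    return (lh - rh) / total


@dataclass
class AsymmetryLimits:
    """Normative AI mean/SD of healthy controls and derived limits.

    ``thresholds[level] = (lo, hi)`` with lo/hi = mean -/+ z*SD for
    z in {2, 3}. Computed from healthy-control scans only.
    """

    metric: str
    hc_mean_ai: float
    hc_sd_ai: float
    n_hc: int
    thresholds: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    @classmethod
    def from_mean_sd(cls, metric: str, mean: float, sd: float, n: int
                     ) -> "AsymmetryLimits":
        if sd <= 0:
            raise ValueError("AI standard deviation must be positive")
        thr = {f"{z}SD": (mean - z * sd, mean + z * sd) for z in (2, 3)}
        return cls(metric=metric, hc_mean_ai=mean, hc_sd_ai=sd, n_hc=n,
                   thresholds=thr)


def fit_normative_limits(hc_ai: Sequence[float], metric: str = "volume"
                         ) -> AsymmetryLimits:
    """Mean and sample SD (ddof=1) over all healthy-control AI values.

    All control scans — including repeat scans — enter the estimate.
    Requires at least 10 values with nonzero spread.
    """
    ai = np.asarray(list(hc_ai), dtype=float)
    if len(ai) < 10:
        raise ValueError(f"need >= 10 healthy-control AI values, got {len(ai)}")
    if np.ptp(ai) == 0:
        raise ValueError("healthy-control AI values have zero spread")
    sd = float(np.std(ai, ddof=1))
    return AsymmetryLimits.from_mean_sd(metric, float(ai.mean()), sd, len(ai))


def classify_by_asymmetry(ai: float, limits: AsymmetryLimits,
                          level: str = "3SD", metric: str | None = None) -> str:
    """Flag a scan as within-norm / left-abnormal / right-abnormal.

    ``metric`` defaults to the limits' own metric and selects the sign
    convention from :data:`METRIC_DIRECTIONS`. For a "decrease" metric
    (volume), AI below the lower limit means the left side is abnormally
    small -> left-abnormal; for an "increase" metric (S/V ratio), AI above
    the upper limit means the left side is abnormally irregular ->
    left-abnormal.
    """
    if level not in limits.thresholds:
        raise KeyError(f"unknown limit level {level!r}; have {sorted(limits.thresholds)}")
    metric = limits.metric if metric is None else metric
    try:
        direction = METRIC_DIRECTIONS[metric]
    except KeyError:
        raise KeyError(f"no sign convention registered for metric {metric!r}") from None
    lo, hi = limits.thresholds[level]
    if lo < ai < hi:
        return WITHIN_NORM
    below = ai <= lo
    if direction == "decrease":
        return LEFT_ABNORMAL if below else RIGHT_ABNORMAL
    return RIGHT_ABNORMAL if below else LEFT_ABNORMAL


@dataclass
class ClassificationOutcome:
    """Aggregate accuracy of abnormality flags on the unilateral-HS vs
    all-other-epilepsies contrast (positive class = unilateral HS,
    predicted-positive = any abnormal flag)."""

    sensitivity: float
    specificity: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int
    n: int


def binary_metrics(predictions: Sequence[str], groups: Sequence[str]
                   ) -> ClassificationOutcome:
    """Sensitivity, specificity and F1 of per-scan abnormality flags.

    Only scans whose group is unilateral HS or ``EPI-other`` enter the
    contrast; HC and bilateral-HS scans are dropped. F1 is defined as 0
    when there are no predicted positives (0/0 convention).
    """
    if len(predictions) != len(groups):
        raise ValueError("predictions and groups must have equal length")
    tp = fp = tn = fn = 0
    for pred, group in zip(predictions, groups):
        if group in UNILATERAL_HS_GROUPS:
            positive = True
        elif group == "EPI-other":
            positive = False
        else:
            continue
        flagged = pred != WITHIN_NORM
        if positive and flagged:
            tp += 1
        elif positive:
            fn += 1
        elif flagged:
            fp += 1
        else:
            tn += 1
    n = tp + fp + tn + fn
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be present in the contrast")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    return ClassificationOutcome(sensitivity=sens, specificity=spec, f1=f1,
                                 tp=tp, fp=fp, tn=tn, fn=fn, n=n)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC of ``scores`` for the positive class (label 1).

    Equals the Mann-Whitney U statistic normalized by n_pos * n_neg, with
    ties counted 1/2 — i.e. the probability that a random positive scores
    above a random negative. Invariant under strictly monotone transforms
    of the scores.
    """
    s = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(labels), dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)  # midranks handle ties as 1/2
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
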