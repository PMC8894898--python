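"""Normative volume model and effect sizes.

Hippocampal volumes are corrected for head size and age by ordinary least
squares fitted on healthy controls only, vol ~ eTIV + age, with both
covariates z-scored using the healthy-control sample statistics. The fitted
model is then applied to every scan: the covariate effect is subtracted
while the intercept is retained, so corrected volumes stay in mm^3. Sex is
deliberately not a covariate. Group differences are summarized with
pooled-SD Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np

from .io import ScanRecord

__all__ = ["NormativeModel", "EffectSize", "fit_normative_model",
           "correct_volume", "cohens_d"]

_SIDE_INDEX = {"lh": 0, "rh": 1}


@dataclass
class NormativeModel:
    """OLS fit of a volume on z-scored eTIV and age in healthy controls.

    Betas are in mm^3 per healthy-control SD of the covariate. The z-scoring
    constants (``mean_*``, ``sd_*``) come from the same healthy-control rows
    the model was fitted on, and are stored so the model can be applied to
    any subject.
    """

    metric: str
    side: str
    intercept: float
    beta_etiv: float
    beta_age: float
    mean_etiv: float
    sd_etiv: float
    mean_age: float
    sd_age: float
    residual_sd: float
    n_fit: int

    def zscores(self, etiv: float, age: float) -> tuple:
        return ((etiv - self.mean_etiv) / self.sd_etiv,
                (age - self.mean_age) / self.sd_age)


@dataclass
class EffectSize:
    """Pooled-SD Cohen's d with the group sizes it was computed from."""

    d: float
    n1: int
    n2: int


def _side_value(record: ScanRecord, metric: str, side: str) -> float:
    try:
        pair = record.measures[metric]
    except KeyError:
        raise KeyError(f"scan {record.scan_id} has no measure {metric!r}") from None
    return float(pair[_SIDE_INDEX[side]])


def fit_normative_model(records: Iterable[ScanRecord], metric: str = "volume",
                        side: str = "lh") -> NormativeModel:
    """Fit vol ~ z(eTIV) + z(age) on the healthy controls among ``records``.

    Non-HC records are ignored. Requires at least 10 HC rows and
    non-constant covariates. Z-scoring uses the HC sample mean and
    sample SD (ddof=1).
    """
    if side not in _SIDE_INDEX:
        raise ValueError(f"side must be 'lh' or 'rh', got {side!r}")
    hc = [r for r in records if r.group == "HC"]
    if len(hc) < 10:
        raise ValueError(f"need >= 10 healthy-control records, got {len(hc)}")
    y = np.array([_side_value(r, metric, side) for r in hc])
    etiv = np.array([r.etiv for r in hc])
    age = np.array([r.age for r in hc])
    sd_etiv = float(np.std(etiv, ddof=1))
    sd_age = float(np.std(age, ddof=1))
    if sd_etiv == 0 or sd_age == 0:
        raise ValueError("constant covariate: cannot z-score eTIV/age")
    z_etiv = (etiv - etiv.mean()) / sd_etiv
    z_age = (age - age.mean()) / sd_age
    X = np.column_stack([np.ones_like(y), z_etiv, z_age])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(len(y) - 3, 1)
    return NormativeModel(
        metric=metric, side=side,
        intercept=float(coef[0]), beta_etiv=float(coef[1]), beta_age=float(coef[2]),
        mean_etiv=float(etiv.mean()), sd_etiv=sd_etiv,
        mean_age=float(age.mean()), sd_age=sd_age,
        residual_sd=float(np.sqrt(resid @ resid / dof)),
        n_fit=len(y),
    )


def correct_volume(record: ScanRecord, model: NormativeModel) -> float:
    """Volume with the covariate effect removed, intercept retained (mm^3).

    corrected = observed - beta_etiv * z(eTIV) - beta_age * z(age),
    z-scores taken with the model's stored healthy-control constants. A scan
    exactly at the HC covariate means is returned unchanged.
    """
    observed = _side_value(record, model.metric, model.side)
    z_etiv, z_age = model.zscores(record.etiv, record.age)
    return observed - model.beta_etiv * z_etiv - model.beta_age * z_age


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> EffectSize:
    """Pooled-SD standardized mean difference, d = (mean_a - mean_b) / s_p.

    s_p^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2), sample variances.
    By convention callers pass the patient group first, so hippocampal
    volume loss in left HS yields a negative d against controls.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    n1, n2 = len(a), len(b)
    s2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if s2 <= 0:
        raise ValueError("pooled standard deviation is zero")
    return EffectSize(d=float((a.mean() - b.mean()) / np.sqrt(s2)), n1=n1, n2=n2)
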