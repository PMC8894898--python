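"""Test-retest robustness: session-wise MAPE, ICC(2,1), paired comparisons.

A *session* groups the repeat scans of one subject: patients' scans on the
same calendar day, healthy controls' scans within one year (greedy
chronological chaining from the earliest unassigned scan). Robustness of a
metric is summarized by

* MAPE — for each session, the mean absolute deviation of its measurements
  from the within-session mean, relative to that mean; averaged over
  sessions and expressed in percent:
  MAPE = (100/N) sum_i (1/n_i) sum_t |m_it - mu_i| / mu_i
* ICC(2,1) — intraclass correlation from a two-way random-effects ANOVA
  with absolute agreement, single-measurement form, computed on the first
  two scans of every session.

Methods are compared by two-sided paired t-tests on the per-session
percentage deviations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats

from .io import ScanRecord

__all__ = ["Session", "RobustnessResult", "build_sessions",
           "per_session_errors", "mape", "icc_2_1", "icc_2_1_from_table",
           "compare_methods_paired"]

HC_SESSION_WINDOW_DAYS = 365


@dataclass
class Session:
    """Repeat scans of one subject forming a test-retest unit.

    ``scan_ids`` are ordered by scan date, ties broken by lexicographic
    scan_id, so "the first two scans" is well-defined.
    """

    subject_id: str
    session_id: str
    scan_ids: List[str]

    @property
    def n_scans(self) -> int:
        return len(self.scan_ids)


@dataclass
class RobustnessResult:
    metric: str
    mape: float  # percent
    icc: float
    n_sessions: int


def build_sessions(records: Sequence[ScanRecord]) -> List[Session]:
    """Group repeat scans into sessions; only sessions with >= 2 scans.

    Patients: scans of one subject on the same calendar day form a session.
    Healthy controls: starting from a subject's earliest unassigned scan,
    all scans within 365 days of that anchor are absorbed into one session;
    the next unassigned scan anchors the next session.
    """
    by_subject: Dict[str, List[ScanRecord]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, []).append(r)

    sessions: List[Session] = []
    for subject_id in sorted(by_subject):
        scans = sorted(by_subject[subject_id], key=lambda r: (r.scan_date, r.scan_id))
        groups: List[List[ScanRecord]] = []
        if scans[0].is_patient:
            by_day: Dict[object, List[ScanRecord]] = {}
            for s in scans:
                by_day.setdefault(s.scan_date, []).append(s)
            groups = [by_day[d] for d in sorted(by_day)]
        else:
            current: List[ScanRecord] = []
            anchor = None
            for s in scans:
                if anchor is not None and (s.scan_date - anchor).days <= HC_SESSION_WINDOW_DAYS:
                    current.append(s)
                else:
                    if current:
                        groups.append(current)
                    current = [s]
                    anchor = s.scan_date
            if current:
                groups.append(current)
        for i, g in enumerate(groups):
            if len(g) >= 2:
                sessions.append(Session(
                    subject_id=subject_id,
                    session_id=f"{subject_id}-s{i}",
                    scan_ids=[s.scan_id for s in g]))
    return sessions


def per_session_errors(sessions: Sequence[Session],
                       values: Mapping[str, float]) -> np.ndarray:
    """Per-session mean absolute percentage deviation from the session mean.

    This is the inner sum of the MAPE definition for each session,
    expressed in percent; :func:`mape` is its average.
    """
    if not sessions:
        raise ValueError("no sessions")
    out = np.empty(len(sessions))
    for i, sess in enumerate(sessions):
        m = np.array([values[sid] for sid in sess.scan_ids], dtype=float)
        mu = m.mean()
        if mu == 0:
            raise ZeroDivisionError(f"session {sess.session_id} has zero mean")
        out[i] = 100.0 * np.mean(np.abs(m - mu) / mu)
    return out


def mape(sessions: Sequence[Session], values: Mapping[str, float]) -> float:
    """Session-averaged mean absolute percentage error (percent)."""
    return float(per_session_errors(sessions, values).mean())


def icc_2_1_from_table(data: np.ndarray) -> float:
    """ICC(2,1) from an (n_subjects, k_raters) table of measurements.

    Two-way random effects, absolute agreement, single measurement:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with MSR/MSC/MSE the between-row, between-column and residual mean
    squares of the two-way ANOVA decomposition.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need an (n >= 2, k >= 2) table")
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise ZeroDivisionError("degenerate table: zero total variance")
    return float((msr - mse) / denom)


def icc_2_1(sessions: Sequence[Session], values: Mapping[str, float]) -> float:
    """ICC(2,1) over sessions using the first two scans of each session."""
    if len(sessions) < 2:
        raise ValueError("ICC requires at least 2 sessions")
    table = np.array([[values[s.scan_ids[0]], values[s.scan_ids[1]]]
                      for s in sessions])
    return icc_2_1_from_table(table)


def compare_methods_paired(errors_by_method: Mapping[str, Sequence[float]]
                           ) -> Dict[Tuple[str, str], float]:
    """Two-sided paired t-tests on per-session errors for each method pair.

    All methods must supply errors for the same sessions in the same order
    (>= 3 sessions). Identical error vectors (zero-variance differences)
    yield p = 1.0 by convention: there is no evidence of a difference.
    """
    methods = sorted(errors_by_method)
    lengths = {len(errors_by_method[m]) for m in methods}
    if len(lengths) != 1:
        raise ValueError("methods must cover the same sessions")
    (n,) = lengths
    if n < 3:
        raise ValueError("paired comparison needs >= 3 sessions")
    pvals: Dict[Tuple[str, str], float] = {}
    for m1, m2 in combinations(methods, 2):
        diff = np.asarray(errors_by_method[m1], float) - np.asarray(errors_by_method[m2], float)
        if np.allclose(diff.std(ddof=1), 0):
            pvals[(m1, m2)] = 1.0 if np.allclose(diff, 0) else 0.0
            continue
        pvals[(m1, m2)] = float(stats.ttest_rel(errors_by_method[m1],
                                                errors_by_method[m2]).pvalue)
    return pvals
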