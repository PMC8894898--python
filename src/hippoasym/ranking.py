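"""Shape-feature importance ranking via a linear max-margin classifier.

Which of the 14 shape descriptors best separates hippocampal-sclerosis
scans from other epilepsies? Each scan contributes the *absolute*
asymmetry index of every shape feature — sclerosis may affect either
hemisphere, so for a linear classifier pooling left- and right-sided cases
it is the magnitude of the asymmetry, not its sign, that carries the
disease signal. A linear SVM (C = 1, the conventional default) is
fitted over 20 repeats of 5-fold cross-validation, with folds stratified by
patient so that all scans of one subject stay on the same side of every
train/test split. Per fit, the absolute weight vector (on within-fold
standardized inputs) is normalized to sum 1; importances are averaged over
all 100 fits and ranked.

Healthy controls are not part of this analysis — the contrast is HS
patients versus all-other-epilepsies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from sklearn.svm import SVC

from .asymmetry import asymmetry_index
from .io import ScanRecord
from .shape import FEATURE_NAMES

__all__ = ["FeatureRanking", "rank_shape_features", "feature_ai_matrix"]


@dataclass
class FeatureRanking:
    """Mean normalized |weight| per feature with its rank (1 = most important)."""

    features: Tuple[str, ...]
    importances: np.ndarray  # non-negative, sums to 1
    ranks: np.ndarray        # permutation of 1..n_features
    n_repeats: int
    n_folds: int
    n_fits: int

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.features, self.importances.tolist()))

    def top_feature(self) -> str:
        return self.features[int(np.argmin(self.ranks))]


def feature_ai_matrix(records: Sequence[ScanRecord],
                      features: Sequence[str] = FEATURE_NAMES
                      ) -> np.ndarray:
    """(n_scans, n_features) matrix of per-feature asymmetry indices."""
    X = np.empty((len(records), len(features)))
    for i, rec in enumerate(records):
        for j, name in enumerate(features):
            if name not in rec.measures:
                raise KeyError(f"scan {rec.scan_id} lacks feature {name!r}")
            lh, rh = rec.measures[name]
            X[i, j] = asymmetry_index(lh, rh)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    return X


def _patient_folds(subjects: np.ndarray, n_folds: int,
                   rng: np.random.Generator) -> List[np.ndarray]:
    """Shuffle unique subjects and split them into n_folds balanced groups."""
    uniq = np.unique(subjects)
    perm = rng.permutation(uniq)
    return [np.asarray(chunk) for chunk in np.array_split(perm, n_folds)]


def rank_shape_features(records: Sequence[ScanRecord], seed: int,
                        n_folds: int = 5, n_repeats: int = 20,
                        features: Sequence[str] = FEATURE_NAMES
                        ) -> FeatureRanking:
    """Rank feature-AI importances for HS vs all-other-epilepsies.

    Healthy-control records are ignored; every remaining scan is labelled
    positive when its group is any HS variant. Requires at least two
    patients per class. Deterministic given ``seed``: fold shuffles come
    from a generator seeded by it, and the SVM fit itself is deterministic.

    Fold draws that leave a training fold single-class are rejected and
    redrawn (up to 100 attempts per repeat).
    """
    patients = [r for r in records if r.is_patient]
    if not patients:
        raise ValueError("no patient records")
    X = np.abs(feature_ai_matrix(patients, features))
    y = np.array([1 if r.group.startswith("HS") else 0 for r in patients])
    subjects = np.array([r.subject_id for r in patients])
    for cls in (0, 1):
        if len(np.unique(subjects[y == cls])) < 2:
            raise ValueError("need >= 2 patients per class")

    rng = np.random.default_rng(seed)
    importances = []
    for _ in range(n_repeats):
        repeat_rng = np.random.default_rng(rng.integers(0, 2**31))
        for _attempt in range(100):
            folds = _patient_folds(subjects, n_folds, repeat_rng)
            ok = True
            for fold_subjects in folds:
                train = ~np.isin(subjects, fold_subjects)
                if len(np.unique(y[train])) < 2:
                    ok = False
                    break
            if ok:
                break
        else:
            raise RuntimeError("could not draw folds with both classes in training")
        for fold_subjects in folds:
            train = ~np.isin(subjects, fold_subjects)
            # patient stratification: no subject straddles the boundary
            assert not (set(subjects[train]) & set(fold_subjects))
            Xt = X[train]
            mu = Xt.mean(axis=0)
            sd = Xt.std(axis=0)
            sd[sd == 0] = 1.0  # constant feature carries no weight anyway
            clf = SVC(kernel="linear", C=1.0)
            clf.fit((Xt - mu) / sd, y[train])
            w = np.abs(clf.coef_[0])
            total = w.sum()
            importances.append(w / total if total > 0 else np.full_like(w, 1 / len(w)))

    mean_imp = np.mean(importances, axis=0)
    mean_imp = mean_imp / mean_imp.sum()
    order = np.argsort(-mean_imp, kind="stable")
    ranks = np.empty(len(mean_imp), dtype=int)
    ranks[order] = np.arange(1, len(mean_imp) + 1)
    return FeatureRanking(features=tuple(features), importances=mean_imp,
                          ranks=ranks, n_repeats=n_repeats, n_folds=n_folds,
                          n_fits=len(importances))
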