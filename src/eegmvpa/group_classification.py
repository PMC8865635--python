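"""HC vs. MCI classification from multivariate EEG activation patterns.

A subject's activation pattern at a time point is the channels x stimuli
matrix of trial-averaged responses (63 x 32 under the default design).
Group discrimination runs a linear SVM (C = 1) in leave-one-subject-out
cross-validation; the reported accuracy is the mean over bootstrap
resamples that subsample participants without replacement from each group,
and significance against chance uses the add-one bootstrap p-value. The
same machinery classifies groups from subjects' RDM upper triangles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .containers import EpochedDataset
from .rdm import upper_triangle
from .stats import TestResult, bootstrap_test, fdr_correct

__all__ = [
    "GroupClassificationResult", "activation_pattern",
    "leave_one_subject_out_accuracy", "classify_groups_timepoint",
    "classify_groups_timecourse", "classify_groups_from_rdms",
]

CHANCE = 0.5


@dataclass
class GroupClassificationResult:
    """Group-classification accuracy over time with inference annotations."""

    times_ms: np.ndarray
    accuracy: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    p_adjusted: np.ndarray
    flags: np.ndarray
    n_bootstrap: int
    metadata: dict = field(default_factory=dict)


def activation_pattern(subject: EpochedDataset, time_ms: float,
                       channel_subset: Sequence[int] | None = None) -> np.ndarray:
    """Channels x stimuli activation-pattern matrix at one time point.

    Column j is the mean over repetition trials of stimulus j's channel
    responses; ``channel_subset`` restricts the rows to a scalp region.
    """
    ti = subject.time_index(time_ms)
    X_t = subject.data[:, :, ti]
    if channel_subset is not None:
        idx = np.asarray(list(channel_subset), dtype=int)
        if idx.size == 0:
            raise ValueError("channel subset is empty")
        X_t = X_t[:, idx]
    stims = subject.unique_stimuli()
    cols = []
    for s in stims:
        rows = np.flatnonzero(subject.stimulus_ids == s)
        if rows.size == 0:
            raise ValueError(f"stimulus {s} has no trials")
        cols.append(X_t[rows].mean(axis=0))
    return np.stack(cols, axis=1)


def leave_one_subject_out_accuracy(feats_a: np.ndarray, feats_b: np.ndarray,
                                   C: float = 1.0) -> float:
    """Leave-one-subject-out CV accuracy of a linear SVM on two groups.

    Folds are paired: each fold holds out one subject from *each* group and
    trains on the rest (subjects of the larger group beyond the pairing
    always train). Pairing keeps every test set class-balanced, so any
    majority-class bias a slightly imbalanced training set induces cancels
    instead of dragging a null accuracy below chance. The held-out subjects
    contribute nothing to training.
    """
    A = np.atleast_2d(np.asarray(feats_a, dtype=float))
    B = np.atleast_2d(np.asarray(feats_b, dtype=float))
    n_folds = min(len(A), len(B))
    if n_folds < 2:
        raise ValueError("need at least 2 subjects per group")
    X = np.concatenate([A, B])
    y = np.concatenate([np.zeros(len(A)), np.ones(len(B))])
    if np.allclose(X, X[0]):
        warnings.warn("identical subject features; returning chance accuracy")
        return CHANCE
    svm = SVC(kernel="linear", C=C)
    correct = 0
    for k in range(n_folds):
        test_idx = np.array([k, len(A) + k])
        mask = np.ones(len(X), dtype=bool)
        mask[test_idx] = False
        svm.fit(X[mask], y[mask])
        correct += int(np.sum(svm.predict(X[test_idx]) == y[test_idx]))
    return correct / (2 * n_folds)


def _split_by_group(features: np.ndarray, labels: np.ndarray):
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("expected exactly two group labels")
    return {g: features[labels == g] for g in uniq}, uniq


def classify_groups_timepoint(features: np.ndarray, labels: np.ndarray,
                              n_boot: int = 10_000, rng=None,
                              subsample_fraction: float = 0.8,
                              C: float = 1.0) -> TestResult:
    """Bootstrap HC vs. MCI classification from per-subject feature vectors.

    ``features`` is (subjects x features) — e.g. flattened activation
    patterns — aligned with ``labels``. Each bootstrap draw subsamples
    participants without replacement from both groups and scores
    leave-one-subject-out CV; the statistic is the full-sample CV accuracy,
    the p-value tests the resample distribution against chance, and the
    reported accuracy (in ``extras``) is the resample mean.
    """
    features = np.asarray(features, dtype=float)
    by_group, names = _split_by_group(features, labels)
    for g, feats in by_group.items():
        if len(feats) < 2:
            raise ValueError(f"group {g!r} needs at least 2 subjects")

    def cv_accuracy(a, b):
        return leave_one_subject_out_accuracy(a, b, C=C)

    res = bootstrap_test((by_group[names[0]], by_group[names[1]]),
                         cv_accuracy, baseline=CHANCE, n=n_boot,
                         side="greater", rng=rng,
                         subsample_fraction=subsample_fraction,
                         return_distribution=False)
    res.method = "bootstrap-group-classification"
    res.extras["accuracy"] = res.extras["boot_mean"]
    return res


def classify_groups_timecourse(subjects: list[EpochedDataset],
                               labels: Sequence[str],
                               times_ms: Sequence[float],
                               channel_subset: Sequence[int] | None = None,
                               n_boot: int = 10_000, alpha: float = 0.05,
                               rng=None, subsample_fraction: float = 0.8,
                               C: float = 1.0) -> GroupClassificationResult:
    """HC vs. MCI classification from activation patterns at each time point,
    FDR-corrected across time."""
    labels = np.asarray(labels)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    times = np.asarray(times_ms, dtype=float)
    acc = np.empty(times.size)
    lo = np.empty(times.size)
    hi = np.empty(times.size)
    p_raw = np.empty(times.size)
    for i, t in enumerate(times):
        feats = np.stack([activation_pattern(s, t, channel_subset).ravel()
                          for s in subjects])
        res = classify_groups_timepoint(feats, labels, n_boot=n_boot, rng=gen,
                                        subsample_fraction=subsample_fraction,
                                        C=C)
        acc[i] = res.extras["accuracy"]
        lo[i], hi[i] = res.extras["ci95"]
        p_raw[i] = res.p_value
    flags, p_adj = fdr_correct(p_raw, alpha=alpha)
    return GroupClassificationResult(
        times_ms=times, accuracy=acc, ci_low=lo, ci_high=hi,
        p_values=p_raw, p_adjusted=p_adj, flags=flags, n_bootstrap=n_boot,
        metadata={"channel_subset": None if channel_subset is None
                  else list(map(int, channel_subset))})


def classify_groups_from_rdms(rdms: np.ndarray, labels: Sequence[str],
                              n_boot: int = 10_000, rng=None,
                              subsample_fraction: float = 0.8,
                              C: float = 1.0) -> TestResult:
    """Discriminate groups from subjects' RDMs at one time point.

    Features are the upper-triangle vectors of the per-subject RDMs; the
    classifier, resampling and inference match
    :func:`classify_groups_timepoint`.
    """
    rdms = np.asarray(rdms)
    feats = upper_triangle(rdms)
    res = classify_groups_timepoint(feats, labels, n_boot=n_boot, rng=rng,
                                    subsample_fraction=subsample_fraction, C=C)
    res.method = "bootstrap-rdm-group-classification"
    return res
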