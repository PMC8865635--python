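"""Pairwise-decoding representational dissimilarity matrices (RDMs).

The RDM cell (i, j) at a time point is the leave-one-trial-out
cross-validated accuracy of a linear SVM discriminating stimulus i from
stimulus j using the scalp-channel patterns of their repetition trials —
0.5 means indiscriminable, 1.0 perfectly discriminable. The matrix is
symmetric with a zero diagonal.

Group-level analyses compare the HC and MCI mean RDMs by the Euclidean
distance between their upper triangles over time (with a permutation test
at the maximum), flag individual cells by rank-sum across subjects with FDR
correction over the 496 cells, and visualize representational geometry by
metric MDS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from sklearn.manifold import smacof
from sklearn.svm import SVC

from .containers import EpochedDataset
from .stats import TestResult, fdr_correct, permutation_test, ranksum_test

__all__ = [
    "RDMDistanceResult", "compute_rdm", "compute_rdm_series",
    "pairwise_accuracy", "rdm_distance_timecourse", "scale_distance",
    "rdm_cellwise_comparison", "mds_embed", "upper_triangle",
]


@dataclass
class RDMDistanceResult:
    """Distance between group-mean RDMs over time, raw and scaled."""

    times_ms: np.ndarray
    distance: np.ndarray              # raw Euclidean distance per time point
    scaled: np.ndarray                # monotone rescaling into [0, 1]
    anchors: tuple[float, float, float]   # (min, baseline, max)
    max_time_ms: float
    max_distance: float
    test: TestResult | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def p_value(self) -> float | None:
        return self.test.p_value if self.test is not None else None


def upper_triangle(rdm: np.ndarray) -> np.ndarray:
    """Off-diagonal upper-triangle cells as a flat vector."""
    rdm = np.asarray(rdm)
    iu = np.triu_indices(rdm.shape[-1], k=1)
    return rdm[..., iu[0], iu[1]]


def pairwise_accuracy(X_i: np.ndarray, X_j: np.ndarray, C: float = 1.0) -> float:
    """Leave-one-trial-out SVM accuracy for one stimulus pair.

    ``X_i`` / ``X_j`` are (trials x channels) response patterns of the two
    stimuli at one time point; every trial is held out once.
    """
    if len(X_i) < 2 or len(X_j) < 2:
        raise ValueError("each stimulus needs at least 2 repetition trials")
    X = np.concatenate([X_i, X_j])
    y = np.concatenate([np.zeros(len(X_i)), np.ones(len(X_j))])
    if np.allclose(X, X[0]):
        warnings.warn("identical trial patterns; pair accuracy set to chance")
        return 0.5
    svm = SVC(kernel="linear", C=C)
    correct = 0
    for k in range(len(X)):
        mask = np.ones(len(X), dtype=bool)
        mask[k] = False
        svm.fit(X[mask], y[mask])
        correct += int(svm.predict(X[k:k + 1])[0] == y[k])
    return correct / len(X)


def compute_rdm(subject: EpochedDataset, time_ms: float,
                C: float = 1.0) -> np.ndarray:
    """Pairwise-decoding RDM of one subject at one time point."""
    ti = subject.time_index(time_ms)
    X_t = subject.data[:, :, ti]
    stims = subject.unique_stimuli()
    trials = {s: X_t[subject.stimulus_ids == s] for s in stims}
    for s, tr in trials.items():
        if len(tr) < 2:
            raise ValueError(f"stimulus {s} has fewer than 2 repetition trials")
    n = len(stims)
    rdm = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            acc = pairwise_accuracy(trials[stims[a]], trials[stims[b]], C=C)
            rdm[a, b] = rdm[b, a] = acc
    return rdm


def compute_rdm_series(subject: EpochedDataset, times_ms: Sequence[float],
                       C: float = 1.0) -> np.ndarray:
    """RDMs of one subject at several time points: (times x stim x stim)."""
    return np.stack([compute_rdm(subject, t, C=C) for t in times_ms])


def rdm_distance_timecourse(hc_rdms: np.ndarray, mci_rdms: np.ndarray,
                            times_ms: Sequence[float],
                            n_perm: int = 10_000, rng=None,
                            baseline_image: float = 0.5,
                            test_time_ms: float | None = None) -> RDMDistanceResult:
    """Euclidean distance between group-mean RDMs per time point.

    Inputs are (subjects x times x stim x stim) stacks with aligned time
    axes and stimulus sets. The distance is computed on upper triangles of
    the group means; its maximum over time is located, and the distance is
    tested by permuting subjects' group labels — at the maximum's time
    point by default, or at ``test_time_ms`` when given (testing at the
    data-selected maximum is mildly anti-conservative; a pre-specified
    time point avoids the selection). Scaled distances use anchors
    (0, mean pre-stimulus distance, max distance); when no pre-stimulus
    time point is available the midpoint of the range anchors the
    baseline.
    """
    hc = np.asarray(hc_rdms)
    mci = np.asarray(mci_rdms)
    times = np.asarray(times_ms, dtype=float)
    if hc.shape[1:] != mci.shape[1:]:
        raise ValueError("groups must share time axis and stimulus set")
    if hc.shape[1] != times.size:
        raise ValueError("times_ms must match the RDM time axis")

    hc_ut = upper_triangle(hc)    # subj x time x cells
    mci_ut = upper_triangle(mci)
    d = np.linalg.norm(hc_ut.mean(axis=0) - mci_ut.mean(axis=0), axis=-1)

    i_max = int(np.argmax(d))
    d_max = float(d[i_max])

    pre = times < 0
    d_base = float(d[pre].mean()) if np.any(pre) else 0.5 * (d.min() + d_max)
    anchors = (float(d.min()), d_base, d_max)
    if anchors[0] < anchors[1] < anchors[2]:
        scaled = np.array([scale_distance(v, anchors,
                                          baseline_image=baseline_image)
                           for v in d])
    else:  # degenerate (e.g. identical cohorts): nothing to rescale
        scaled = np.zeros_like(d)

    def group_distance(a, b):
        return float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))

    if test_time_ms is None:
        i_test = i_max
    else:
        i_test = int(np.argmin(np.abs(times - test_time_ms)))
    test = permutation_test(hc_ut[:, i_test, :], mci_ut[:, i_test, :],
                            statistic_fn=group_distance, n=n_perm,
                            side="greater", rng=rng)
    return RDMDistanceResult(times_ms=times, distance=d, scaled=scaled,
                             anchors=anchors, max_time_ms=float(times[i_max]),
                             max_distance=d_max, test=test,
                             metadata={"test_time_ms": float(times[i_test])})


def scale_distance(d: float, anchors: tuple[float, float, float],
                   baseline_image: float = 0.5) -> float:
    """Monotone logarithmic rescaling of a distance into [0, 1].

    The map is f(d) = log(1 + (d - d_min)/kappa) / log(1 + (d_max - d_min)/kappa),
    which sends the minimum anchor to 0 and the maximum to 1; ``kappa`` is
    fitted so the baseline anchor maps to ``baseline_image``. A concave log
    map can only place the baseline above its linear image
    (d_base - d_min)/(d_max - d_min); an infeasible request falls back to
    the linear map with a warning. Distances outside the anchor range are
    clamped (with a warning).
    """
    d_min, d_base, d_max = anchors
    if not d_min < d_base < d_max:
        raise ValueError("anchors must satisfy min < baseline < max")
    if d < d_min or d > d_max:
        warnings.warn(f"distance {d} outside anchor range; clamping")
        d = float(np.clip(d, d_min, d_max))
    span = d_max - d_min
    linear_image = (d_base - d_min) / span

    def image(kappa: float) -> float:
        return np.log1p((d_base - d_min) / kappa) / np.log1p(span / kappa)

    if baseline_image <= linear_image or baseline_image >= 1.0:
        warnings.warn(
            f"baseline image {baseline_image} not attainable by a concave "
            f"log map (feasible range ({linear_image:.3g}, 1)); using the "
            "linear map")
        return (d - d_min) / span

    lo, hi = span * 1e-9, span * 1e9
    # image(kappa) decreases from 1 (kappa -> 0) to linear_image (kappa -> inf)
    kappa = brentq(lambda k: image(k) - baseline_image, lo, hi)
    return float(np.log1p((d - d_min) / kappa) / np.log1p(span / kappa))


def rdm_cellwise_comparison(hc_rdms: np.ndarray, mci_rdms: np.ndarray,
                            alpha: float = 0.05):
    """Rank-sum comparison of every upper-triangle RDM cell across subjects.

    Inputs are per-subject RDMs at a single time point
    (subjects x stim x stim). FDR correction runs over all off-diagonal
    cells (496 for 32 stimuli). Returns symmetric boolean flag and adjusted
    p-value matrices.
    """
    hc = np.asarray(hc_rdms)
    mci = np.asarray(mci_rdms)
    if hc.shape[1:] != mci.shape[1:]:
        raise ValueError("groups must share the stimulus set")
    n = hc.shape[-1]
    iu = np.triu_indices(n, k=1)
    hc_ut = hc[:, iu[0], iu[1]]
    mci_ut = mci[:, iu[0], iu[1]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tied cells warn individually
        p_raw = np.array([ranksum_test(hc_ut[:, c], mci_ut[:, c]).p_value
                          for c in range(hc_ut.shape[1])])
    flags_ut, p_adj_ut = fdr_correct(p_raw, alpha=alpha)
    flags = np.zeros((n, n), dtype=bool)
    p_adj = np.ones((n, n))
    flags[iu] = flags_ut
    flags.T[iu] = flags_ut
    p_adj[iu] = p_adj_ut
    p_adj.T[iu] = p_adj_ut
    return flags, p_adj


def _classical_mds_init(rdm: np.ndarray, dims: int) -> np.ndarray:
    """Classical (Torgerson) MDS coordinates used to initialize SMACOF."""
    n = rdm.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (rdm ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dims]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return coords


def mds_embed(rdm: np.ndarray, dims: int = 2, seed: int = 0):
    """Metric MDS embedding of the stimuli.

    Classical-scaling initialization refined by SMACOF stress majorization.
    Returns ``(coordinates, stress)`` where stress is the raw SMACOF value.
    """
    rdm = np.asarray(rdm, dtype=float)
    if rdm.ndim != 2 or rdm.shape[0] != rdm.shape[1]:
        raise ValueError("RDM must be a square matrix")
    if not np.allclose(rdm, rdm.T, atol=1e-10):
        raise ValueError("RDM must be symmetric")
    init = _classical_mds_init(rdm, dims)
    coords, stress = smacof(rdm, n_components=dims, init=init, n_init=1,
                            metric=True, random_state=seed,
                            normalized_stress=False)
    return coords, float(stress)
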