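"""Event-related potentials and univariate group comparisons.

An ERP here is the trial-average voltage time course, averaged again over
the channels of a named scalp region; the cohort ERP is the mean of the
per-subject ERPs. Group comparisons are non-parametric: per-time-point
Wilcoxon tests with Benjamini-Hochberg FDR correction across the tested
family (time points within a region, or regions at a fixed time point), and
percentile-bootstrap confidence bands for the group difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ChannelGroupMap, EpochedDataset
from .stats import fdr_correct, ranksum_test, signrank_test

__all__ = [
    "ErpResult", "ErpComparison", "compute_erp", "cohort_erp",
    "erp_significance_vs_baseline", "erp_group_difference",
]


@dataclass
class ErpResult:
    """Per-subject region ERPs: region name -> waveform over the epoch."""

    region_waveforms: dict[str, np.ndarray]
    times_ms: np.ndarray
    metadata: dict = field(default_factory=dict)

    def regions(self) -> list[str]:
        return list(self.region_waveforms)

    def as_array(self, regions: list[str] | None = None) -> np.ndarray:
        """Stack waveforms into a (regions x time) array."""
        regions = regions or self.regions()
        return np.stack([self.region_waveforms[r] for r in regions])


@dataclass
class ErpComparison:
    """HC-minus-MCI difference waveform with inference annotations."""

    difference: np.ndarray        # mean(HC) - mean(MCI) per time point
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray          # per-time-point rank-sum p
    p_adjusted: np.ndarray
    flags: np.ndarray             # FDR-significant time points


def compute_erp(epochs: EpochedDataset, group_map: ChannelGroupMap) -> ErpResult:
    """Region-level ERP of one subject.

    Averages over trials first, then over the channels of each region.
    """
    if epochs.n_trials == 0:
        raise ValueError("cannot compute an ERP from an empty dataset")
    group_map.validate_against(epochs.n_channels)
    evoked = epochs.data.mean(axis=0)  # channels x time
    waves = {region: evoked[group_map[region]].mean(axis=0)
             for region in group_map}
    return ErpResult(region_waveforms=waves, times_ms=epochs.times_ms.copy(),
                     metadata=dict(epochs.metadata))


def cohort_erp(results: list[ErpResult], region: str) -> np.ndarray:
    """Per-subject waveforms of one region stacked as (subjects x time)."""
    return np.stack([r.region_waveforms[region] for r in results])


def erp_significance_vs_baseline(values: np.ndarray, alpha: float = 0.05):
    """Signed-rank test of per-subject values against zero, FDR-corrected.

    ``values`` is (subjects x family), where the family axis is whatever set
    of comparisons is corrected together (time points, or regions at the
    decoding-peak time point). Returns ``(flags, p_adjusted, p_raw)``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if values.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    p_raw = np.array([signrank_test(values[:, j]).p_value
                      for j in range(values.shape[1])])
    flags, p_adj = fdr_correct(p_raw, alpha=alpha)
    return flags, p_adj, p_raw


def erp_group_difference(hc_values: np.ndarray, mci_values: np.ndarray,
                         alpha: float = 0.05, n_boot: int = 10_000,
                         rng=None) -> ErpComparison:
    """Compare two cohorts' ERPs per time point.

    Rank-sum at each time point with FDR correction across time, plus a
    percentile-bootstrap 95% confidence band (resampling subjects with
    replacement within each group) for the HC-minus-MCI difference.
    """
    hc = np.atleast_2d(np.asarray(hc_values, dtype=float))
    mci = np.atleast_2d(np.asarray(mci_values, dtype=float))
    if hc.shape[0] < 2 or mci.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if hc.shape[1] != mci.shape[1]:
        raise ValueError("groups must share the time axis")
    n_time = hc.shape[1]
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    p_raw = np.array([ranksum_test(hc[:, t], mci[:, t]).p_value
                      for t in range(n_time)])
    flags, p_adj = fdr_correct(p_raw, alpha=alpha)

    diff = hc.mean(axis=0) - mci.mean(axis=0)
    boot = np.empty((n_boot, n_time))
    for b in range(n_boot):
        hi = gen.integers(0, hc.shape[0], size=hc.shape[0])
        mi = gen.integers(0, mci.shape[0], size=mci.shape[0])
        boot[b] = hc[hi].mean(axis=0) - mci[mi].mean(axis=0)
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5], axis=0)

    return ErpComparison(difference=diff, ci_low=ci_low, ci_high=ci_high,
                         p_values=p_raw, p_adjusted=p_adj, flags=flags)
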