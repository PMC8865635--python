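"""Non-parametric inference primitives.

All resampling tests share the add-one p-value convention

    p = (number of resampled statistics on the null side + 1) / (n + 1)

so a resampling p-value is never zero and its smallest attainable value is
exactly ``1 / (n + 1)`` (``1/10001 ≈ 0.0001`` at the default 10,000
resamples). Rank tests delegate to scipy, FDR correction to statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult", "bootstrap_test", "permutation_test",
    "ranksum_test", "signrank_test", "fdr_correct", "ttest_from_summary",
]


@dataclass
class TestResult:
    """Outcome of a statistical test, serializable to a tidy record."""

    statistic: float
    p_value: float
    method: str
    side: str = "two-sided"
    n_resamples: int | None = None
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")

    def to_record(self) -> dict:
        rec = {"statistic": self.statistic, "p_value": self.p_value,
               "method": self.method, "side": self.side,
               "n_resamples": self.n_resamples, "seed": self.seed}
        rec.update(self.extras)
        return rec


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _resample_p(count_null_side: int, n: int) -> float:
    return (count_null_side + 1) / (n + 1)


def _subsample(rng: np.random.Generator, x: np.ndarray, fraction: float) -> np.ndarray:
    k = max(2, int(np.ceil(fraction * len(x))))
    k = min(k, len(x))
    idx = rng.choice(len(x), size=k, replace=False)
    return x[idx]


def bootstrap_test(samples, statistic_fn: Callable, baseline: float,
                   n: int = 10_000, side: str = "greater", rng=None,
                   subsample_fraction: float = 0.8,
                   return_distribution: bool = True) -> TestResult:
    """One-sample bootstrap test against a fixed baseline.

    ``samples`` is one array (or a tuple of per-group arrays). Each of the
    ``n`` resamples draws ``ceil(subsample_fraction * len)`` elements without
    replacement from each group and evaluates ``statistic_fn`` on the draw;
    the p-value counts resampled statistics on the null side of ``baseline``:
    at or below it when ``side="greater"`` (alternative: statistic above
    baseline), at or above it when ``side="less"``.

    The bootstrap distribution is retained in ``extras`` (percentile 95% CI
    and bootstrap SE are always reported).
    """
    if side not in ("greater", "less"):
        raise ValueError("side must be 'greater' or 'less'")
    if n < 1:
        raise ValueError("need at least one resample")
    if not isinstance(samples, tuple):
        samples = (samples,)
    groups = [np.asarray(s) for s in samples]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty sample")
    gen = _as_rng(rng)

    observed = float(statistic_fn(*groups))
    boot = np.empty(n)
    for i in range(n):
        draws = [_subsample(gen, g, subsample_fraction) for g in groups]
        boot[i] = statistic_fn(*draws)

    if side == "greater":
        count = int(np.sum(boot <= baseline))
    else:
        count = int(np.sum(boot >= baseline))
    p = _resample_p(count, n)

    lo, hi = np.percentile(boot, [2.5, 97.5])
    extras = {"ci95": (float(lo), float(hi)),
              "se": float(np.std(boot, ddof=1)) if n > 1 else 0.0,
              "boot_mean": float(boot.mean()), "baseline": baseline}
    if return_distribution:
        extras["distribution"] = boot
    return TestResult(statistic=observed, p_value=p, method="bootstrap",
                      side=side, n_resamples=n, extras=extras)


def _two_sample_default_stat(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(x) - np.mean(y))


def permutation_test(x, y, statistic_fn: Callable | None = None,
                     n: int = 10_000, side: str = "two-sided", rng=None,
                     exact: bool | None = None) -> TestResult:
    """Two-sample permutation test by random (or exhaustive) relabeling.

    The null distribution is built by relabeling the pooled observations into
    groups of the original sizes. With ``exact=True`` (or automatically when
    the total number of distinct relabelings is at most ``n``) every
    relabeling is enumerated and the p-value is the exact tail proportion;
    otherwise ``n`` random relabelings are drawn and the add-one formula
    applies.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    stat = statistic_fn or _two_sample_default_stat
    observed = float(stat(x, y))
    pooled = np.concatenate([x, y])
    n_x, n_tot = len(x), len(pooled)
    n_combos = comb(n_tot, n_x)
    if exact is None:
        exact = n_combos <= n

    def tail_count(null: np.ndarray) -> int:
        if side == "greater":
            return int(np.sum(null >= observed))
        if side == "less":
            return int(np.sum(null <= observed))
        if side == "two-sided":
            return int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
        raise ValueError(f"unknown side {side!r}")

    if exact:
        null = np.empty(n_combos)
        idx_all = np.arange(n_tot)
        for i, xs in enumerate(combinations(idx_all, n_x)):
            mask = np.zeros(n_tot, dtype=bool)
            mask[list(xs)] = True
            null[i] = stat(pooled[mask], pooled[~mask])
        p = tail_count(null) / n_combos
        method = "permutation-exact"
        n_used = n_combos
    else:
        gen = _as_rng(rng)
        null = np.empty(n)
        for i in range(n):
            perm = gen.permutation(n_tot)
            null[i] = stat(pooled[perm[:n_x]], pooled[perm[n_x:]])
        p = _resample_p(tail_count(null), n)
        method = "permutation"
        n_used = n
        alpha_floor = 1.0 / (n + 1)
        if alpha_floor > 0.05:
            warnings.warn(f"only {n} permutations: smallest attainable "
                          f"p-value is {alpha_floor:.3g}")
    return TestResult(statistic=observed, p_value=float(p), method=method,
                      side=side, n_resamples=n_used,
                      extras={"null_distribution": null})


def ranksum_test(x, y, side: str = "two-sided") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test for equal location.

    Uses the exact null distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise (scipy's automatic choice).
    All-tied data returns p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("all observations tied; rank-sum p-value set to 1")
        return TestResult(statistic=float(len(x) * len(y) / 2), p_value=1.0,
                          method="ranksum", side=side)
    res = sps.mannwhitneyu(x, y, alternative=side, method="auto")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="ranksum", side=side)


def signrank_test(x, side: str = "two-sided") -> TestResult:
    """Wilcoxon signed-rank test of symmetric location at zero.

    Constant-zero input has no information; it returns p = 1 with a warning
    rather than raising, so per-time-point significance maps degrade
    gracefully on flat data.
    """
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("sample must be non-empty")
    if np.all(x == 0):
        warnings.warn("all observations zero; signed-rank p-value set to 1")
        return TestResult(statistic=0.0, p_value=1.0, method="signrank", side=side)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on zeros/ties
        res = sps.wilcoxon(x, alternative=side, zero_method="wilcox")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="signrank", side=side)


def fdr_correct(p_values: Sequence[float], alpha: float = 0.05):
    """Benjamini-Hochberg step-up FDR correction.

    Returns ``(flags, adjusted_p)`` aligned with the input; empty input
    yields empty arrays.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    flags, adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return flags, adj


def ttest_from_summary(mean1: float, sd1: float, n1: int,
                       mean2: float, sd2: float, n2: int,
                       welch: bool = False) -> TestResult:
    """Two-sided two-sample t-test from summary statistics.

    Pooled-variance (Student) by default; set ``welch=True`` for unequal
    variances. Used to check group-comparability tables that report only
    means, SDs and group sizes.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                   equal_var=not welch)
    method = "welch-t" if welch else "pooled-t"
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method=method, side="two-sided")
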