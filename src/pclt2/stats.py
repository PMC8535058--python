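"""Paired statistics for the unloaded-vs-loaded comparison.

The battery mirrors standard musculoskeletal-MRI practice: lengths are
compared with the two-tailed paired Student's t-test (normality is a
reasonable assumption for a macroscopic distance); T2 summary statistics
and texture features with the Wilcoxon signed-rank test; the three
ligament subregions with Friedman's test followed by Dunn's multiple
comparison; and the study's minimum sample size comes from a
noncentral-t power computation. The significance level defaults to
alpha = 0.01 to contain clinically insignificant findings.

Wilcoxon p-values are exact for n <= 25 (full enumeration of the 2^n
sign assignments via the rank-sum generating function), with the Pratt
treatment of zero differences (zeros are ranked, then dropped from the
statistic); larger samples use the normal approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "DunnResult",
    "paired_ttest",
    "wilcoxon_paired",
    "friedman_dunn",
    "minimum_sample_size",
    "power_two_sample_t",
    "power_paired_t",
]

ALPHA_DEFAULT = 0.01


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    n: int
    alpha: float = ALPHA_DEFAULT

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p_value <= self.alpha)


@dataclass
class DunnResult:
    pair: tuple[str, str]
    z: float
    p_uncorrected: float
    p_bonferroni: float


def paired_ttest(x0: np.ndarray, x1: np.ndarray, alpha: float = ALPHA_DEFAULT) -> TestResult:
    """Two-tailed paired Student's t-test on x1 - x0.

    Identical vectors give t = 0, p = 1. A nonzero constant difference
    (zero variance) is degenerate: reported as p = 0 with a warning.
    """
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    if x0.shape != x1.shape or x0.ndim != 1:
        raise ValueError("paired samples must be 1D of equal length")
    n = len(x0)
    if n < 2:
        raise ValueError("need >= 2 pairs")
    d = x1 - x0
    if np.ptp(d) == 0:
        if d[0] == 0:
            return TestResult("paired t", 0.0, 1.0, n, alpha)
        warnings.warn("zero-variance nonzero differences; paired t degenerate, p -> 0")
        return TestResult("paired t", np.inf if d[0] > 0 else -np.inf, 0.0, n, alpha)
    t, p = sps.ttest_rel(x1, x0)
    return TestResult("paired t", float(t), float(p), n, alpha)


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic by enumerating the
    2^m sign assignments through the generating function of the rank sums.

    ``ranks`` are the (possibly mid-) ranks of the nonzero differences;
    they are doubled so half-integer mid-ranks become integers.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1, dtype=np.float64)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(np.rint(2 * w_plus))
    lower = dist[: w2 + 1].sum()
    upper = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_paired(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = ALPHA_DEFAULT,
    zero_method: str = "pratt",
    exact_max_n: int = 25,
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples (y vs x).

    Exact enumeration for n <= ``exact_max_n`` nonzero differences;
    normal approximation above. All-zero differences give p = 1 with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1D of equal length")
    n = len(x)
    if n < 5:
        raise ValueError("need >= 5 pairs for the signed-rank test")
    d = y - x
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1")
        return TestResult("wilcoxon signed-rank", 0.0, 1.0, n, alpha)

    all_ranks = sps.rankdata(np.abs(d))  # zeros ranked (Pratt), mid-ranks for ties
    nonzero = d != 0
    if zero_method != "pratt":
        all_ranks = sps.rankdata(np.abs(d[nonzero]))
        ranks = all_ranks
        signs = np.sign(d[nonzero])
    else:
        ranks = all_ranks[nonzero]
        signs = np.sign(d[nonzero])
    w_plus = float(ranks[signs > 0].sum())
    m = int(nonzero.sum())
    if m <= exact_max_n:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        mean = ranks.sum() / 2.0
        var = (ranks**2).sum() / 4.0
        z = (w_plus - mean) / np.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
    return TestResult("wilcoxon signed-rank", w_plus, min(p, 1.0), n, alpha)


def friedman_dunn(
    blocks: np.ndarray,
    labels: tuple[str, ...] = ("PR", "CR", "DR"),
    alpha: float = ALPHA_DEFAULT,
    always_posthoc: bool = False,
) -> tuple[TestResult, list[DunnResult]]:
    """Friedman test across k related groups, Dunn post-hoc when significant.

    ``blocks`` is (n_specimens, k) with complete rows. Dunn compares
    Friedman rank sums pairwise, z = |R_i - R_j| / sqrt(n k (k+1) / 6),
    reporting both the uncorrected and the Bonferroni-corrected p across
    the k(k-1)/2 pairs. Post-hocs are computed when the overall p <= alpha
    (or unconditionally with ``always_posthoc``).
    """
    blocks = np.asarray(blocks, dtype=float)
    if blocks.ndim != 2 or blocks.shape[1] != len(labels):
        raise ValueError(f"blocks must be (n, {len(labels)})")
    if np.isnan(blocks).any():
        raise ValueError("incomplete blocks (NaN values) are not allowed")
    n, k = blocks.shape
    if n < 2:
        raise ValueError("need >= 2 complete blocks")

    ranks = np.apply_along_axis(sps.rankdata, 1, blocks)
    rank_sums = ranks.sum(axis=0)
    if np.ptp(rank_sums) == 0 and np.allclose(ranks, ranks[:, :1]):
        overall = TestResult("friedman", 0.0, 1.0, n, alpha)
    else:
        stat, p = sps.friedmanchisquare(*blocks.T)
        overall = TestResult("friedman", float(stat), float(p), n, alpha)

    pairwise: list[DunnResult] = []
    if always_posthoc or overall.significant:
        se = np.sqrt(n * k * (k + 1) / 6.0)
        n_pairs = k * (k - 1) // 2
        for i, j in combinations(range(k), 2):
            z = abs(rank_sums[i] - rank_sums[j]) / se
            p_unc = float(2 * sps.norm.sf(z))
            pairwise.append(
                DunnResult(
                    pair=(labels[i], labels[j]),
                    z=float(z),
                    p_uncorrected=p_unc,
                    p_bonferroni=float(min(1.0, n_pairs * p_unc)),
                )
            )
    return overall, pairwise


def power_two_sample_t(n_per_group: int, effect_size: float, alpha: float = 0.05) -> float:
    """Power of the two-sample two-tailed t-test at Cohen's d."""
    df = 2 * n_per_group - 2
    if df < 1:
        return 0.0
    nc = effect_size * np.sqrt(n_per_group / 2.0)
    crit = sps.t.ppf(1 - alpha / 2, df)
    return _nct_two_tail(crit, df, nc)


def power_paired_t(n: int, effect_size: float, alpha: float = 0.05) -> float:
    """Power of the paired two-tailed t-test at d_z = mean(diff)/sd(diff)."""
    df = n - 1
    if df < 1:
        return 0.0
    nc = effect_size * np.sqrt(n)
    crit = sps.t.ppf(1 - alpha / 2, df)
    return _nct_two_tail(crit, df, nc)


def _nct_two_tail(crit: float, df: float, nc: float) -> float:
    """P(|T| > crit) for noncentral t; survival-function form to stay
    numerically stable at large noncentrality."""
    upper = sps.nct.sf(crit, df, nc)
    lower = sps.nct.cdf(-crit, df, nc)
    if np.isnan(upper):
        upper = 1.0 if nc > crit else 0.0
    if np.isnan(lower):
        lower = 0.0
    return float(min(1.0, upper + lower))


def minimum_sample_size(
    power: float = 0.8,
    alpha: float = 0.05,
    effect_size: float = 1.6,
    tails: str = "two",
    design: str = "two-sample",
    n_max: int = 1_000_000,
) -> int:
    """Smallest per-group n reaching the target power at Cohen's d.

    Two-tailed two-sample design by default (the convention of the
    standard sample-size calculators for an effect size stated as
    Cohen's d between two groups).
    """
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must lie in (0, 1)")
    if effect_size <= 0:
        raise ValueError("effect size must be positive")
    if tails != "two":
        raise NotImplementedError("only the two-tailed design is provided")
    if design == "two-sample":
        fn, n_min = power_two_sample_t, 2
    elif design == "paired":
        fn, n_min = power_paired_t, 2
    else:
        raise ValueError(f"unknown design {design!r}")
    for n in range(n_min, n_max + 1):
        if fn(n, effect_size, alpha) >= power:
            return n
    raise ValueError(f"power {power} unreachable at d={effect_size} within n <= {n_max}")
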