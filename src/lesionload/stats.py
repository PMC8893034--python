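"""Nonparametric and parametric statistics for cohort comparisons.

Wraps the standard kernels (Spearman's rho, Pearson's r, tie-corrected
Kruskal-Wallis) in result records carrying n, df and two-tailed p, and
adds Dunn-type pairwise post-hoc comparisons on the pooled ranks with
Bonferroni multiplication — the "adjusted significance" convention of
classical statistics packages. All tests are two-tailed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "KwResult",
    "PairwiseComparison",
    "spearman",
    "spearman_exact_p",
    "pearson",
    "kruskal_wallis",
    "pairwise_posthoc",
    "bonferroni_alpha",
]


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "spearman" | "pearson"
    coefficient: float
    n: int
    p_two_tailed: float

    @property
    def df(self) -> int:
        return self.n - 2


@dataclass(frozen=True)
class KwResult:
    h: float  # tie-corrected H statistic
    df: int
    p: float  # chi-square approximation
    group_sizes: tuple[int, ...]


@dataclass(frozen=True)
class PairwiseComparison:
    pair: str  # e.g. "Good-Poor"
    median_difference: float
    z: float
    p_raw: float
    p_adjusted: float  # min(1, raw * number of pairs)


def _check_xy(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be 1-D of equal length, got {x.shape}, {y.shape}")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return x, y


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    Two-tailed p from the t approximation ``t = r sqrt((n-2)/(1-r^2))``
    on n-2 degrees of freedom.
    """
    x, y = _check_xy(x, y, min_n=4)
    r, p = sps.spearmanr(x, y)
    return CorrelationResult("spearman", float(r), len(x), float(p))


def spearman_exact_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-tailed permutation p for Spearman's rho (small n only).

    Enumerates all n! rank permutations; the p-value is the fraction with
    |rho| at least as extreme as observed. Intended as a cross-check of
    the t approximation for n <= 8.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n > 8:
        raise ValueError("exact enumeration limited to n <= 8")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, np.asarray(perm))[0, 1]
        count += abs(r) >= obs - 1e-12
        total += 1
    return count / total


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with two-tailed t-based p."""
    x, y = _check_xy(x, y, min_n=3)
    r, p = sps.pearsonr(x, y)
    return CorrelationResult("pearson", float(r), len(x), float(p))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KwResult:
    """Tie-corrected Kruskal-Wallis H test across independent groups.

    p comes from the chi-square approximation on (groups - 1) degrees of
    freedom. If every pooled value is identical, H = 0 by convention (no
    evidence of any difference) rather than an error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    sizes = tuple(len(g) for g in groups)
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return KwResult(0.0, df, 1.0, sizes)
    h, p = sps.kruskal(*groups)
    return KwResult(float(h), df, float(p), sizes)


def pairwise_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    adjust: str = "bonferroni",
) -> list[PairwiseComparison]:
    """Dunn-type pairwise comparisons after a Kruskal-Wallis test.

    Each pair is compared with a z statistic on the pooled, tie-corrected
    ranks:

        z = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j) )

    with tie term ``T = sum(t^3 - t)`` over tied-value groups. Raw p is
    two-tailed normal; the adjusted p multiplies by the number of pairs
    (Bonferroni) and caps at 1. The median difference reported is
    ``median(group_i) - median(group_j)``.
    """
    if adjust != "bonferroni":
        raise ValueError(f"unsupported adjustment {adjust!r}")
    groups = [np.asarray(g, dtype=float) for g in groups]
    kruskal_wallis(groups)  # validates applicability
    g = len(groups)
    labels = list(labels) if labels is not None else [f"G{i + 1}" for i in range(g)]
    if len(labels) != g:
        raise ValueError("one label per group required")

    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    # mean rank per group
    mean_ranks = []
    start = 0
    for grp in groups:
        mean_ranks.append(ranks[start:start + len(grp)].mean())
        start += len(grp)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var_base = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        var_base -= tie_term / (12.0 * (n_total - 1))

    n_pairs = g * (g - 1) // 2
    out = []
    for i, j in itertools.combinations(range(g), 2):
        se = math.sqrt(var_base * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        if se == 0:  # all pooled values tied
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
        med_diff = float(np.median(groups[i]) - np.median(groups[j]))
        out.append(
            PairwiseComparison(
                pair=f"{labels[i]}-{labels[j]}",
                median_difference=med_diff,
                z=float(z),
                p_raw=float(p_raw),
                p_adjusted=min(1.0, float(p_raw) * n_pairs),
            )
        )
    return out


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-comparison significance threshold alpha/m."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of comparisons must be >= 1, got {m}")
    return alpha / m
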