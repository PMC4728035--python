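"""Tie-corrected Kruskal-Wallis rank test, implemented from first principles.

H = [ 12/(N(N+1)) * sum_j R_j^2/n_j - 3(N+1) ] / [ 1 - sum(t^3 - t)/(N^3 - N) ]

with midranks over the pooled sample, R_j the group rank sums and t the
sizes of tied groups. The p-value is the upper tail of the chi-square
distribution with k-1 degrees of freedom; an exact permutation p-value is
available for small samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class RankTestResult:
    H: float
    df: int
    p_value: float
    group_sizes: list[int]
    n_ties: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"H = {self.H:.3f}, df = {self.df}, P = {self.p_value:.4g}"


def midranks(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..N, tied values getting the mean of the ranks they span.

    Sum of the output is exactly N(N+1)/2.
    """
    x = np.asarray(list(values), dtype=float)
    if len(x) == 0:
        raise ValueError("cannot rank an empty sequence")
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        # positions i..j (0-based) share ranks i+1..j+1 -> midrank (i+j)/2 + 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _h_statistic(groups: list[np.ndarray]) -> tuple[float, int]:
    """Tie-corrected H and the number of tied groups in the pooled sample."""
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r_j = ranks[start : start + len(g)].sum()
        h += r_j * r_j / len(g)
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)

    _uniq, counts = np.unique(pooled, return_counts=True)
    tie_sizes = counts[counts > 1]
    correction = 1.0 - float(((tie_sizes**3 - tie_sizes).sum())) / (n_total**3 - n_total)
    if correction == 0.0:
        # every pooled value identical: no evidence of any difference
        return 0.0, len(tie_sizes)
    return h / correction, len(tie_sizes)


def kruskal_wallis(groups: Sequence[Sequence[float]], permutation: int | None = None,
                   seed: int = 0) -> RankTestResult:
    """Compare k independent groups by ranks.

    Parameters
    ----------
    groups:
        At least two nonempty sequences of numbers, total size >= 3.
    permutation:
        When set, additionally estimate the p-value by ``permutation``
        random relabelings instead of the chi-square approximation.
    """
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in arrays):
        raise ValueError("every group must be nonempty")
    n_total = sum(len(g) for g in arrays)
    if n_total < 3:
        raise ValueError("need at least 3 observations in total")

    h, n_ties = _h_statistic(arrays)
    df = len(arrays) - 1
    if h == 0.0:
        p = 1.0
    elif permutation is None:
        p = float(stats.chi2.sf(h, df))
    else:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate(arrays)
        sizes = [len(g) for g in arrays]
        hits = 0
        for _ in range(permutation):
            perm = rng.permutation(pooled)
            pieces, start = [], 0
            for s in sizes:
                pieces.append(perm[start : start + s])
                start += s
            if _h_statistic(pieces)[0] >= h - 1e-12:
                hits += 1
        p = (hits + 1) / (permutation + 1)
    return RankTestResult(
        H=float(max(0.0, h)),
        df=df,
        p_value=min(1.0, p),
        group_sizes=[len(g) for g in arrays],
        n_ties=n_ties,
    )


def compare_land_use(density_matrix) -> RankTestResult:
    """Rank-test the columns of a species x land-use spoor-density table."""
    groups = [density_matrix[c].dropna().to_numpy() for c in density_matrix.columns]
    groups = [g for g in groups if len(g) > 0]
    return kruskal_wallis(groups)
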