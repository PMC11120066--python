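"""Measured-versus-predicted comparison statistics.

Percent differences with per-class summaries, and a from-scratch
two-tailed Mann-Whitney U test.  The exact null distribution is obtained
by full enumeration of labelings for small tied samples and by a
count-distribution recursion for untied samples; larger samples fall back
to the normal approximation with tie and continuity corrections.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ComparisonReport",
    "RankTestResult",
    "percent_difference",
    "summarize_differences",
    "mann_whitney_u",
]

#: samples with pooled size up to this are tested exactly in 'auto' mode
EXACT_THRESHOLD = 12

#: hard cost guard on full enumeration (C(n, n1) labelings)
ENUMERATION_LIMIT = 200_000


@dataclass(frozen=True)
class ComparisonReport:
    """Summary of signed percent differences grouped by class."""

    differences: Mapping[str, tuple[float, ...]]  # signed, per group
    mean_abs_pct: Mapping[str, float]
    sd_abs_pct: Mapping[str, float]
    max_abs_pct: float

    def to_dict(self) -> dict:
        return {
            "groups": {
                str(k): {
                    "mean_abs_pct": self.mean_abs_pct[k],
                    "sd_abs_pct": self.sd_abs_pct[k],
                    "n": len(self.differences[k]),
                }
                for k in self.differences
            },
            "max_abs_pct": self.max_abs_pct,
        }


@dataclass(frozen=True)
class RankTestResult:
    """Two-tailed Mann-Whitney U outcome."""

    u: float
    n1: int
    n2: int
    p: float
    method: str

    def __post_init__(self) -> None:
        if not 0 <= self.u <= self.n1 * self.n2:
            raise ValueError("U outside [0, n1*n2]")
        if not 0 < self.p <= 1:
            raise ValueError("p must lie in (0, 1]")


def percent_difference(measured: float, calculated: float) -> float:
    """Signed percent difference ``100 * (measured - calculated) / calculated``."""
    if calculated == 0:
        raise ValueError("calculated value must be non-zero")
    return 100.0 * (measured - calculated) / calculated


def summarize_differences(
    groups: Mapping[str, Sequence[tuple[float, float]]]
) -> ComparisonReport:
    """Per-group mean/SD of absolute percent differences plus the global max.

    Each group maps to (measured, calculated) pairs; SDs are sample SDs
    (n - 1 denominator), so every group needs at least two pairs.
    """
    diffs: dict[str, tuple[float, ...]] = {}
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    global_max = 0.0
    if not groups:
        raise ValueError("no groups supplied")
    for key, pairs in groups.items():
        if len(pairs) < 2:
            raise ValueError(f"group {key!r} needs at least 2 pairs")
        d = np.array([percent_difference(m, c) for m, c in pairs])
        a = np.abs(d)
        diffs[key] = tuple(float(x) for x in d)
        means[key] = float(a.mean())
        sds[key] = float(a.std(ddof=1))
        global_max = max(global_max, float(a.max()))
    return ComparisonReport(
        differences=diffs, mean_abs_pct=means, sd_abs_pct=sds, max_abs_pct=global_max
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties given their midrank."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def _exact_p_enumeration(pooled: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-tailed p from the full permutation distribution of U."""
    n = len(pooled)
    if math.comb(n, n1) > ENUMERATION_LIMIT:
        raise ValueError("sample too large for full enumeration; use mode='normal'")
    ranks = _midranks(pooled)
    offset = n1 * (n1 + 1) / 2.0
    us = np.array(
        [sum(ranks[list(c)]) - offset for c in itertools.combinations(range(n), n1)]
    )
    total = len(us)
    eps = 1e-9
    p_le = np.sum(us <= u_obs + eps) / total
    p_ge = np.sum(us >= u_obs - eps) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


@functools.lru_cache(maxsize=64)
def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Null counts of the U statistic for untied samples.

    ``counts[u]`` is the number of the C(n1+n2, n1) labelings giving U = u;
    classic generating-function recursion.
    """
    max_u = n1 * n2
    # dp[k][u]: subsets of size k from the first i ranks with U = u
    dp = np.zeros((n1 + 1, max_u + 1), dtype=float)
    dp[0, 0] = 1.0
    for i in range(1, n1 + n2 + 1):
        for k in range(min(i, n1), 0, -1):
            # taking rank i as the k-th x contributes (i - k) to U
            contrib = i - k
            if contrib == 0:
                dp[k, :] += dp[k - 1, :]
            else:
                dp[k, contrib:] += dp[k - 1, :-contrib]
    return dp[n1]


def _exact_p_counts(n1: int, n2: int, u_obs: float) -> float:
    counts = _exact_u_counts(n1, n2)
    total = counts.sum()
    us = np.arange(counts.size)
    eps = 1e-9
    p_le = counts[us <= u_obs + eps].sum() / total
    p_ge = counts[us >= u_obs - eps].sum() / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def _normal_p(pooled: np.ndarray, n1: int, n2: int, u_obs: float) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    diff = u_obs - mu
    if diff > 0.5:
        diff -= 0.5
    elif diff < -0.5:
        diff += 0.5
    else:
        diff = 0.0
    z = diff / math.sqrt(var)
    p = math.erfc(abs(z) / math.sqrt(2.0))  # = 2 * (1 - Phi(|z|))
    return min(1.0, max(p, np.finfo(float).tiny))


def mann_whitney_u(x, y, mode: str = "auto") -> RankTestResult:
    """Two-tailed Mann-Whitney U test with midrank tie handling.

    ``mode``: ``auto`` uses the exact null distribution when the pooled
    size is at most 12, otherwise the normal approximation; ``exact`` and
    ``normal`` force the respective method.  The exact method enumerates
    all labelings for tied data and uses the count recursion otherwise.
    """
    xa = np.asarray(x, float).ravel()
    ya = np.asarray(y, float).ravel()
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    n1, n2 = xa.size, ya.size
    pooled = np.concatenate([xa, ya])
    u_obs = _u_statistic(xa, ya)
    use_exact = mode == "exact" or (mode == "auto" and n1 + n2 <= EXACT_THRESHOLD)
    if use_exact:
        has_ties = len(np.unique(pooled)) < pooled.size
        if has_ties:
            p = _exact_p_enumeration(pooled, n1, u_obs)
        else:
            p = _exact_p_counts(n1, n2, u_obs)
        method = "exact"
    else:
        p = _normal_p(pooled, n1, n2, u_obs)
        method = "normal approximation"
    return RankTestResult(u=float(u_obs), n1=n1, n2=n2, p=float(p), method=method)
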