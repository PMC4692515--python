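"""Group-level non-parametric inference on per-subject decoding summaries.

Exact (enumeration) p-values are used throughout because the sample
sizes in question are small (a dozen subjects): the Wilcoxon signed-rank
null is enumerated by dynamic programming over sign assignments, and the
Mann-Whitney null by enumeration of group assignments.  Ties are handled
with average (mid-)ranks, zero differences are dropped before ranking.
Large-sample normal approximations exist in scipy and serve as
cross-checks, not as the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupTestResult",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "spearman_fdr",
]


@dataclass
class GroupTestResult:
    """One non-parametric test outcome (W, U or rho with its p-value)."""

    statistic_name: str
    statistic_value: float
    p_value: float
    n: tuple[int, ...]
    adjusted_p: float | None = None
    note: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        s = f"{self.statistic_name} = {self.statistic_value:g}, p = {self.p_value:.4g}"
        if self.adjusted_p is not None:
            s += f" (FDR-adjusted p = {self.adjusted_p:.4g})"
        return s


def _signed_rank_pmf(double_ranks: np.ndarray) -> np.ndarray:
    """Exact pmf of the positive-rank sum over all 2^n sign assignments.

    Ranks are doubled so mid-ranks become integers; index s of the
    returned array is the count of sign patterns with doubled W+ = s.
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in double_ranks:
        r = int(r)
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    return counts


def wilcoxon_signed_rank(
    real_acc: np.ndarray, null_mean_acc: np.ndarray
) -> GroupTestResult:
    """Paired Wilcoxon signed-rank test with exact two-sided enumeration p.

    Tests per-subject real accuracies against the same subjects' mean
    permutation accuracies.  Zero differences are dropped (Wilcoxon's
    original treatment); ties among |differences| get average ranks.
    W is the smaller of the two signed-rank sums.  For n <= 25 the
    two-sided p enumerates all sign assignments exactly.
    """
    x = np.asarray(real_acc, dtype=float)
    y = np.asarray(null_mean_acc, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")
    if n < 2:
        raise ValueError("need at least 2 nonzero differences")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    if n <= 25:
        double = np.rint(2 * ranks).astype(int)
        pmf = _signed_rank_pmf(double)
        total = pmf.sum()
        w2 = int(round(2 * w_plus))
        p_le = pmf[: w2 + 1].sum() / total
        p_ge = pmf[w2:].sum() / total
        p = float(min(1.0, 2.0 * min(p_le, p_ge)))
        note = "exact enumeration"
    else:  # pragma: no cover - group sizes here never exceed 25
        p = float(stats.wilcoxon(x, y, zero_method="wilcox", mode="approx").pvalue)
        note = "normal approximation"
    return GroupTestResult("W", w, p, (n,), note=note)


def mann_whitney_u(group_a: np.ndarray, group_b: np.ndarray) -> GroupTestResult:
    """Mann-Whitney U test with exact two-sided enumeration p for small n.

    U is the smaller of the two group statistics (computed from pooled
    mid-ranks, so ties are supported).  For pooled sizes with at most
    200000 group assignments the two-sided p enumerates every assignment;
    larger samples fall back to the tie-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2)
    u_b = float(na * nb - u_a)
    u = min(u_a, u_b)

    if comb(na + nb, na) <= 200_000:
        dist = []
        idx_all = range(na + nb)
        for subset in combinations(idx_all, na):
            dist.append(ranks[list(subset)].sum() - na * (na + 1) / 2)
        dist = np.asarray(dist)
        p_le = np.mean(dist <= u_a + 1e-12)
        p_ge = np.mean(dist >= u_a - 1e-12)
        p = float(min(1.0, 2.0 * min(p_le, p_ge)))
        note = "exact enumeration"
    else:  # pragma: no cover - exercised only for large groups
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        note = "normal approximation"
    return GroupTestResult("U", u, p, (na, nb), note=note)


def spearman_fdr(
    mean_acc: np.ndarray, scores: dict[str, np.ndarray]
) -> dict[str, GroupTestResult]:
    """Spearman correlations of accuracy with questionnaire scales, BH-FDR.

    ``scores`` maps scale names (object / spatial / verbal) to per-subject
    score vectors paired with ``mean_acc``.  Benjamini-Hochberg adjustment
    runs across the scales.  A constant input vector yields an undefined
    (NaN) rho flagged in the result note, with p treated as 1 for the
    adjustment.
    """
    x = np.asarray(mean_acc, dtype=float)
    if len(scores) == 0:
        raise ValueError("no questionnaire scales supplied")
    names = list(scores)
    results: dict[str, GroupTestResult] = {}
    raw_p = []
    for name in names:
        y = np.asarray(scores[name], dtype=float)
        if y.shape != x.shape:
            raise ValueError(f"scale {name!r} length does not match accuracies")
        if len(x) < 4:
            raise ValueError("need at least 4 paired observations per scale")
        if np.all(x == x[0]) or np.all(y == y[0]):
            results[name] = GroupTestResult(
                "rho", float("nan"), 1.0, (len(x),), note="constant input; rho undefined"
            )
            raw_p.append(1.0)
            continue
        rho, p = stats.spearmanr(x, y)
        results[name] = GroupTestResult("rho", float(rho), float(p), (len(x),))
        raw_p.append(float(p))
    _, p_adj, _, _ = multipletests(raw_p, method="fdr_bh")
    for name, adj in zip(names, p_adj):
        results[name].adjusted_p = float(adj)
    return results
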