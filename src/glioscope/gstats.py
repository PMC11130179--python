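"""Nonparametric group comparisons with Bonferroni correction.

Two-group comparisons use the two-tailed Wilcoxon rank-sum test (exact
enumeration of the rank-sum distribution for n + m <= 12, tie-corrected
normal approximation otherwise).  Three or more groups use the Kruskal-Wallis
omnibus test followed by pairwise rank-sum comparisons flagged at a
Bonferroni-corrected level alpha / (number of pairs); Dunn-style z follow-ups
on the pooled ranks are available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import defaults

__all__ = [
    "ComparisonResult",
    "wilcoxon_ranksum",
    "kruskal_wallis_mc",
    "comparison_table",
]

EXACT_MAX_N = 12


@dataclass
class ComparisonResult:
    """One two-group comparison with its corrected significance decision."""

    group_a: str
    group_b: str
    test: str
    statistic: float
    p_value: float
    alpha: float = defaults.ALPHA
    n_comparisons: int = 1

    @property
    def corrected_alpha(self) -> float:
        return self.alpha / self.n_comparisons

    @property
    def significant(self) -> bool:
        return self.p_value < self.corrected_alpha


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-tailed exact rank-sum p by enumerating all C(n+m, n) assignments.

    Midranks handle ties.  Returns (rank-sum statistic of sample a, p).
    """
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n = len(a)
    w_obs = ranks[:n].sum()
    sums = []
    for idx in combinations(range(len(pooled)), n):
        sums.append(ranks[list(idx)].sum())
    sums = np.asarray(sums)
    tol = 1e-9
    p_low = np.mean(sums <= w_obs + tol)
    p_high = np.mean(sums >= w_obs - tol)
    return float(w_obs), float(min(1.0, 2.0 * min(p_low, p_high)))


def wilcoxon_ranksum(a, b, labels: tuple[str, str] = ("a", "b"),
                     alpha: float = defaults.ALPHA,
                     n_comparisons: int = 1) -> ComparisonResult:
    """Two-tailed Wilcoxon rank-sum (Mann-Whitney) comparison of two samples.

    Exact enumeration when n + m <= 12 (handles ties via midranks);
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.size + b.size <= EXACT_MAX_N:
        stat, p = _exact_ranksum_p(a, b)
        test = "wilcoxon_ranksum_exact"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        stat, p = float(res.statistic), float(res.pvalue)
        test = "wilcoxon_ranksum_normal"
    return ComparisonResult(group_a=labels[0], group_b=labels[1], test=test,
                            statistic=stat, p_value=p, alpha=alpha,
                            n_comparisons=n_comparisons)


def _dunn_pairwise(groups: dict) -> list[tuple[str, str, float, float]]:
    """Dunn-style z tests on pooled ranks, tie-corrected."""
    labels = sorted(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    sizes = {g: len(groups[g]) for g in labels}
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    mean_ranks, i = {}, 0
    for g in labels:
        mean_ranks[g] = ranks[i:i + sizes[g]].mean()
        i += sizes[g]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1))
    out = []
    for g1, g2 in combinations(labels, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        out.append((g1, g2, float(z), float(p)))
    return out


def kruskal_wallis_mc(groups: dict, alpha: float = defaults.ALPHA,
                      followup: str = "ranksum"):
    """Kruskal-Wallis omnibus test with Bonferroni-corrected pairwise follow-ups.

    ``groups`` maps label -> sample (each with >= 2 values; >= 3 groups).
    Returns ``(omnibus, results)``: the omnibus dict carries the tie-corrected
    H statistic and its p-value; ``results`` lists one
    :class:`ComparisonResult` per pair, each judged at alpha / (# pairs).
    ``followup`` selects "ranksum" (pairwise Wilcoxon rank-sum) or "dunn"
    (z tests on the pooled ranks).
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups; use wilcoxon_ranksum for two")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if any(v.size < 2 for v in arrays.values()):
        raise ValueError("each group needs at least 2 values")
    h, p_omni = sps.kruskal(*[arrays[g] for g in sorted(arrays)])
    omnibus = {"test": "kruskal_wallis", "H": float(h), "p_value": float(p_omni),
               "n_groups": len(arrays)}
    pairs = list(combinations(sorted(arrays), 2))
    results = []
    if followup == "dunn":
        for g1, g2, z, p in _dunn_pairwise(arrays):
            results.append(ComparisonResult(
                group_a=g1, group_b=g2, test="dunn_z", statistic=z,
                p_value=p, alpha=alpha, n_comparisons=len(pairs)))
    elif followup == "ranksum":
        for g1, g2 in pairs:
            r = wilcoxon_ranksum(arrays[g1], arrays[g2], labels=(g1, g2),
                                 alpha=alpha, n_comparisons=len(pairs))
            results.append(r)
    else:
        raise ValueError("followup must be 'ranksum' or 'dunn'")
    return omnibus, results


def comparison_table(results: list[ComparisonResult]) -> pd.DataFrame:
    """Tidy table of comparison results (one row per pair)."""
    return pd.DataFrame([{
        "group_a": r.group_a,
        "group_b": r.group_b,
        "test": r.test,
        "statistic": r.statistic,
        "p_value": r.p_value,
        "alpha": r.alpha,
        "n_comparisons": r.n_comparisons,
        "corrected_alpha": r.corrected_alpha,
        "significant": r.significant,
    } for r in results])
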