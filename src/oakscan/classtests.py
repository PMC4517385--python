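"""Gene-class selection scans: Wilcoxon rank-sum tests per Pfam accession
against all other genes, with Benjamini-Hochberg FDR across accessions.

The scanned statistic is any per-gene value (geometric-mean dN/dS or
median Fay & Wu's H); sentinel ratios participate as ordinary values,
which rank-based tests tolerate.  Tests are two-sided with the direction
(class median above/below background) reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "wilcoxon_rank_sum",
    "bh_fdr",
    "run_class_scan",
    "ClassTestResult",
    "EXACT_MAX_N",
]

EXACT_MAX_N = 20  # combined sample size up to which the exact null is enumerated


def _rank(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values)


def wilcoxon_rank_sum(
    class_values: Sequence[float], background_values: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of class vs background values.

    Returns (rank-sum statistic W of the class group, p-value).  For
    combined n <= EXACT_MAX_N the null distribution of W is enumerated
    over all rank assignments (exact even with ties); otherwise the
    normal approximation with tie correction is used.  Complete ties
    across both groups give p = 1.
    """
    x = np.asarray(class_values, dtype=float)
    y = np.asarray(background_values, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _rank(pooled)
    w_obs = float(ranks[: len(x)].sum())
    if np.ptp(pooled) == 0.0:
        return (w_obs, 1.0)
    n = len(pooled)
    if n <= EXACT_MAX_N:
        sums = np.array(
            [ranks[list(idx)].sum() for idx in combinations(range(n), len(x))]
        )
        mean = sums.mean()
        p_lo = float(np.mean(sums <= w_obs + 1e-9))
        p_hi = float(np.mean(sums >= w_obs - 1e-9))
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        return (w_obs, p)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return (w_obs, float(res.pvalue))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up Q-values (order-preserving, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


@dataclass
class ClassTestResult:
    accession: str
    n_class: int
    n_background: int
    statistic: float
    pvalue: float
    direction: str  # 'high' or 'low'
    qvalue: float = math.nan
    class_median: float = math.nan
    background_median: float = math.nan


def run_class_scan(
    gene_stats: Mapping[str, float],
    annotations: Mapping[str, set[str] | Sequence[str]],
    min_class_size: int = 5,
) -> list[ClassTestResult]:
    """Test every sufficiently large Pfam class against all other genes.

    ``gene_stats`` maps gene id -> statistic; ``annotations`` maps gene
    id -> Pfam accessions.  A gene with several accessions is a member of
    each of its classes and background for every other class.  Q-values
    are BH-adjusted across the tested accessions of this one scan.
    Results are sorted by Q, then p.
    """
    genes = [g for g in gene_stats if not math.isnan(gene_stats[g])]
    members: dict[str, list[str]] = {}
    for g in genes:
        for acc in annotations.get(g, ()):
            members.setdefault(acc, []).append(g)
    results = []
    for acc in sorted(members):
        in_class = members[acc]
        if len(in_class) < min_class_size:
            continue
        in_set = set(in_class)
        background = [g for g in genes if g not in in_set]
        if not background:
            continue
        x = [gene_stats[g] for g in in_class]
        y = [gene_stats[g] for g in background]
        w, p = wilcoxon_rank_sum(x, y)
        cm, bm = float(np.median(x)), float(np.median(y))
        results.append(
            ClassTestResult(
                accession=acc,
                n_class=len(x),
                n_background=len(y),
                statistic=w,
                pvalue=p,
                direction="high" if cm >= bm else "low",
                class_median=cm,
                background_median=bm,
            )
        )
    if results:
        q = bh_fdr([r.pvalue for r in results])
        for r, qi in zip(results, q):
            r.qvalue = float(qi)
    results.sort(key=lambda r: (r.qvalue, r.pvalue, r.accession))
    return results


def scan_to_frame(results: Sequence[ClassTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "accession": r.accession,
                "n_class": r.n_class,
                "n_background": r.n_background,
                "statistic": r.statistic,
                "pvalue": r.pvalue,
                "qvalue": r.qvalue,
                "direction": r.direction,
                "class_median": r.class_median,
                "background_median": r.background_median,
            }
            for r in results
        ]
    )
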