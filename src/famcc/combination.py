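"""Cross-design evidence combination and the top-K two-step decision rule.

The two study subsets are disjoint, so their per-SNP p-values are
independent and may be pooled with Fisher's method or a sample-size-weighted
Z.  Screening ranks from the two subsets are aggregated by averaging log
ranks (order-equivalent to the rank product), and only the K best aggregate
ranks are tested, at the reduced per-test level alpha/K.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 1e-300


def fisher_combine(p_values) -> float:
    """Fisher's combined probability: X = -2 sum(ln p) ~ chi-square(2k)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("fisher_combine needs at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]; floor exact zeros before calling")
    X = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(X, 2 * p.size))


def fisher_combine_pairwise(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Vectorized two-study Fisher combination; NaN inputs propagate to NaN."""
    p1 = np.clip(np.asarray(p1, dtype=float), P_FLOOR, 1.0)
    p2 = np.clip(np.asarray(p2, dtype=float), P_FLOOR, 1.0)
    X = -2.0 * (np.log(p1) + np.log(p2))
    return stats.chi2.sf(X, 4)


def weighted_z_combine(p_values, directions, sample_sizes) -> float:
    """Sample-size-weighted Z meta-analysis of two-sided p-values.

    Each p is converted to Z_i = Phi^-1(1 - p_i/2) * direction_i and weighted
    by sqrt(N_i); the combined Z is renormalized to unit variance.  p = 1
    maps to Z = 0 regardless of direction.
    """
    p = np.asarray(p_values, dtype=float)
    d = np.asarray(directions, dtype=float)
    n = np.asarray(sample_sizes, dtype=float)
    if not (p.shape == d.shape == n.shape):
        raise ValueError("p_values, directions, sample_sizes must align")
    if np.any(~np.isin(d, (-1.0, 1.0))):
        raise ValueError("directions must be +1 or -1")
    if np.any(n <= 0):
        raise ValueError("sample sizes must be positive")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    z_i = stats.norm.isf(p / 2.0) * d
    z_i = np.where(p == 1.0, 0.0, z_i)
    w = np.sqrt(n)
    Z = (w * z_i).sum() / np.sqrt((w**2).sum())
    return float(2.0 * stats.norm.sf(abs(Z)))


def weighted_z_pairwise(
    p1: np.ndarray, z1: np.ndarray, n1: float, p2: np.ndarray, z2: np.ndarray, n2: float
) -> np.ndarray:
    """Vectorized two-study weighted-Z; directions taken from the signs of z1/z2."""
    p1 = np.clip(np.asarray(p1, dtype=float), P_FLOOR, 1.0)
    p2 = np.clip(np.asarray(p2, dtype=float), P_FLOOR, 1.0)
    zi1 = stats.norm.isf(p1 / 2.0) * np.where(np.asarray(z1) < 0, -1.0, 1.0)
    zi2 = stats.norm.isf(p2 / 2.0) * np.where(np.asarray(z2) < 0, -1.0, 1.0)
    w1, w2 = np.sqrt(n1), np.sqrt(n2)
    Z = (w1 * zi1 + w2 * zi2) / np.sqrt(w1**2 + w2**2)
    return 2.0 * stats.norm.sf(np.abs(Z))


def aggregate_ranks(
    rank_family: np.ndarray, rank_cc: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-log-rank aggregation of two subset rankings.

    score = (ln r_fam + ln r_cc) / 2, ascending — order-equivalent to the
    rank product.  Ties break on the smaller family rank, then input order.
    Ranks must be distinct positive integers per subset (normally a
    permutation of 1..M; larger values are allowed so that a subset ranked
    against a wider universe can still be aggregated).  Returns
    (aggregate_score, aggregate_rank).
    """
    rf = np.asarray(rank_family, dtype=float)
    rc = np.asarray(rank_cc, dtype=float)
    if rf.shape != rc.shape:
        raise ValueError("rank vectors must cover the same SNP set")
    M = len(rf)
    for r in (rf, rc):
        if np.any(r < 1) or len(np.unique(r)) != M:
            raise ValueError("ranks must be distinct integers >= 1")
    score = 0.5 * (np.log(rf) + np.log(rc))
    order = np.lexsort((np.arange(M), rf, score))
    agg = np.empty(M, dtype=np.int64)
    agg[order] = np.arange(1, M + 1)
    return score, agg


def two_step_decision(
    snp_ids: np.ndarray,
    rank_family: np.ndarray,
    rank_cc: np.ndarray,
    p_family: np.ndarray,
    p_cc: np.ndarray,
    K: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Select the K best aggregate-ranked SNPs and test them at alpha/K.

    ``p_family`` is the full-trio transmission-test p (valid because the
    family screen never reads offspring genotypes); ``p_cc`` is the
    testing-table p (valid because the case-control screen saw only disjoint
    subjects plus margins).  Fisher p-values are reported for every SNP, but
    only SNPs with aggregate rank <= K are eligible for significance.
    """
    M = len(snp_ids)
    if not 1 <= K <= M:
        raise ValueError(f"K must be in [1, {M}] (got {K})")
    score, agg_rank = aggregate_ranks(rank_family, rank_cc)
    p_fisher = fisher_combine_pairwise(p_family, p_cc)
    selected = agg_rank <= K
    threshold = alpha / K
    significant = selected & (p_fisher < threshold) & np.isfinite(p_fisher)
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "rank_family": rank_family,
            "rank_cc": rank_cc,
            "aggregate_score": score,
            "aggregate_rank": agg_rank,
            "p_family": p_family,
            "p_cc": p_cc,
            "p_fisher": p_fisher,
            "selected_top_k": selected,
            "significant": significant,
        }
    )
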