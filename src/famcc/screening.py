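"""Screening statistics that are independent of the downstream tests.

Family side: predicted power of the trio test computed from parental
genotypes and offspring phenotypes only — offspring genotypes are never read,
so the subsequent transmission test needs no multiplicity adjustment for the
screen.  Case-control side: subjects are partitioned into a screening table
and a testing table; the testing table's margins plus null-imputed cells are
combined with the screening table to rank SNPs, while the real testing table
is reserved for an orthogonal association test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_data import GenotypeMatrix, TrioSet
from .family_tests import DEFAULT_OFFSET, _transmission_moments
from .population_tests import GenotypeCountTable, _trend_uv, trend_test

DEFAULT_FRACTIONS = (0.75, 0.50, 0.25)


@dataclass
class ScreenScan:
    """Per-SNP screening scores and their 1-based promise ranking."""

    snp_ids: np.ndarray
    score: np.ndarray
    rank: np.ndarray
    degenerate: np.ndarray
    b_hat: np.ndarray | None = None
    delta: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


@dataclass
class ContingencySplit:
    """Screening table + testing table + testing margins for one SNP.

    Cellwise, screening + testing reproduces the full affection-by-genotype
    table.
    """

    screening_a: np.ndarray
    screening_u: np.ndarray
    testing_a: np.ndarray
    testing_u: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.screening_a, self.screening_u, self.testing_a, self.testing_u):
            if np.asarray(arr).shape != (3,) or np.any(np.asarray(arr) < 0):
                raise ValueError("split tables must be non-negative length-3 vectors")

    @property
    def testing_row_totals(self) -> tuple[int, int]:
        return int(self.testing_a.sum()), int(self.testing_u.sum())

    @property
    def testing_col_totals(self) -> np.ndarray:
        return self.testing_a + self.testing_u

    def testing_table(self) -> GenotypeCountTable:
        return GenotypeCountTable(a=self.testing_a, u=self.testing_u)


def _rank_descending(
    score: np.ndarray,
    degenerate: np.ndarray,
    pos: np.ndarray,
    snp_ids: np.ndarray,
) -> np.ndarray:
    """1-based ranks, best score first.

    Ties break deterministically: non-degenerate before degenerate, then
    smaller genomic position, then lexicographic SNP id.
    """
    _, id_codes = np.unique(np.asarray(snp_ids, dtype=str), return_inverse=True)
    order = np.lexsort((id_codes, pos, degenerate.astype(int), -score))
    rank = np.empty(len(score), dtype=np.int64)
    rank[order] = np.arange(1, len(score) + 1)
    return rank


# ---------------------------------------------------------------------------
# Family screen: conditional power from P(Y, S)


def conditional_power_scores(
    father_calls: np.ndarray,
    mother_calls: np.ndarray,
    phenotype: np.ndarray,
    offset: float = DEFAULT_OFFSET,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Predicted power of the trio test at level alpha, per SNP.

    Per SNP: the expected offspring score g_i = E[X_i | parents] serves as a
    genotype proxy; regressing Y on g gives a slope b and residual variance
    s2; with V = sum (Y_i - offset)^2 Var[X_i | parents], the noncentrality
    is delta = b * sqrt(V) / s2 and the power is
    Phi(delta - z_{a/2}) + Phi(-delta - z_{a/2}).

    Inputs are parental call matrices (n_snps, n_trios) and the offspring
    phenotype vector — offspring genotypes are deliberately not accepted.
    Returns (power, b_hat, delta, degenerate).
    """
    f = np.asarray(father_calls)
    m = np.asarray(mother_calls)
    y = np.asarray(phenotype, dtype=float)
    ok = (f >= 0) & (m >= 0)
    n = ok.sum(axis=1).astype(float)

    e, var_x = _transmission_moments(
        np.where(ok, f, 0).astype(float), np.where(ok, m, 0).astype(float)
    )
    g = np.where(ok, e, 0.0)
    yk = np.where(ok, y[None, :], 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        g_mean = g.sum(axis=1) / n
        y_mean = yk.sum(axis=1) / n
        cov_gy = (g * yk).sum(axis=1) / n - g_mean * y_mean
        var_g = (g**2).sum(axis=1) / n - g_mean**2
        var_y = (yk**2).sum(axis=1) / n - y_mean**2
        b_hat = cov_gy / var_g
        resid = var_y - b_hat**2 * var_g
        dof = np.maximum(n - 2.0, 1.0)
        s2 = np.maximum(resid, 0.0) * n / dof

        V = (np.where(ok, (y[None, :] - offset) ** 2, 0.0) * var_x).sum(axis=1)
        delta = b_hat * np.sqrt(V) / s2

    degenerate = ~(var_g > 1e-12) | (n < 3) | ~np.isfinite(delta)
    delta = np.where(degenerate, 0.0, delta)
    b_hat = np.where(degenerate, 0.0, b_hat)

    z = stats.norm.ppf(1.0 - alpha / 2.0)
    power = stats.norm.cdf(delta - z) + stats.norm.cdf(-delta - z)
    power = np.where(degenerate, alpha, power)
    return power, b_hat, delta, degenerate


def conditional_power_screen(
    trios: TrioSet,
    genotypes: GenotypeMatrix,
    offset: float = DEFAULT_OFFSET,
    alpha: float = 0.05,
) -> ScreenScan:
    """Rank SNPs by conditional power over the trio subset.

    Only parental genotype rows are extracted from ``genotypes``; the
    offspring columns never reach the score computation.
    """
    if trios.n_trios == 0:
        raise ValueError("conditional_power_screen requires at least one trio")
    power, b_hat, delta, degenerate = conditional_power_scores(
        genotypes.calls[:, trios.father_idx],
        genotypes.calls[:, trios.mother_idx],
        trios.offspring_phenotype,
        offset=offset,
        alpha=alpha,
    )
    rank = _rank_descending(power, degenerate, genotypes.pos, genotypes.snp_ids)
    return ScreenScan(
        snp_ids=genotypes.snp_ids,
        score=power,
        rank=rank,
        degenerate=degenerate,
        b_hat=b_hat,
        delta=delta,
    )


# ---------------------------------------------------------------------------
# Case-control screen: contingency-table partition


def _round_half_away(x: np.ndarray | float):
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


def c2bat_split(
    case_genotypes: np.ndarray,
    control_genotypes: np.ndarray,
    fractions=DEFAULT_FRACTIONS,
    rng: np.random.Generator | None = None,
) -> ContingencySplit:
    """Partition one SNP's subjects into screening and testing tables.

    Within each genotype class j a simple random sample of
    round(fraction_j * n_j) subjects — drawn from the pooled cases+controls
    of that class, ignoring phenotype — goes to the testing table; the rest
    form the screening table.  Default fractions over-select minor
    homozygotes (0.75/0.50/0.25 for classes 2/1/0 — passed here in class
    order 2, 1, 0).
    """
    rng = np.random.default_rng() if rng is None else rng
    fr = np.asarray(fractions, dtype=float)
    if fr.shape != (3,) or np.any(fr < 0) or np.any(fr > 1):
        raise ValueError("fractions must be three values in [0, 1]")
    # fractions arrive ordered (minor hom, het, major hom) = classes (2, 1, 0)
    frac_by_class = fr[::-1]

    case = np.asarray(case_genotypes)
    ctrl = np.asarray(control_genotypes)
    case = case[case >= 0]
    ctrl = ctrl[ctrl >= 0]

    a_full = np.bincount(case, minlength=3)[:3]
    u_full = np.bincount(ctrl, minlength=3)[:3]
    test_a = np.zeros(3, dtype=np.int64)
    test_u = np.zeros(3, dtype=np.int64)
    for j in range(3):
        n_j = a_full[j] + u_full[j]
        m_j = int(_round_half_away(frac_by_class[j] * n_j))
        if m_j == 0:
            continue
        labels = np.concatenate([np.ones(a_full[j]), np.zeros(u_full[j])])
        pick = rng.permutation(n_j)[:m_j]
        test_a[j] = int(labels[pick].sum())
        test_u[j] = m_j - test_a[j]
    if test_a.sum() + test_u.sum() == 0:
        raise ValueError("empty testing table: fractions select no subjects")
    return ContingencySplit(
        screening_a=a_full - test_a,
        screening_u=u_full - test_u,
        testing_a=test_a,
        testing_u=test_u,
    )


def _impute_affected(
    rng: np.random.Generator, m: np.ndarray, a_total: np.ndarray
) -> np.ndarray:
    """Null-imputed affected counts per genotype column, margins held exactly.

    Sequential hypergeometric draws over columns; supports vectorized input
    with shape (..., 3) column totals and (...,) affected row totals.
    """
    m = np.asarray(m, dtype=np.int64)
    a_total = np.asarray(a_total, dtype=np.int64)
    out = np.zeros(m.shape, dtype=np.int64)
    remaining = a_total.copy()
    tail = m[..., 1] + m[..., 2]
    out[..., 0] = _safe_hypergeometric(rng, m[..., 0], tail, remaining)
    remaining = remaining - out[..., 0]
    out[..., 1] = _safe_hypergeometric(rng, m[..., 1], m[..., 2], remaining)
    out[..., 2] = remaining - out[..., 1]
    return out


def _safe_hypergeometric(rng, ngood, nbad, nsample):
    """rng.hypergeometric tolerant of empty urns (returns 0 there)."""
    ngood = np.asarray(ngood, dtype=np.int64)
    nbad = np.asarray(nbad, dtype=np.int64)
    nsample = np.asarray(nsample, dtype=np.int64)
    total = ngood + nbad
    empty = (total == 0) | (nsample == 0)
    draw = rng.hypergeometric(
        np.where(empty, 0, ngood),
        np.where(empty, 1, nbad),
        np.where(empty, 0, np.minimum(nsample, total)),
    )
    return np.where(empty, 0, draw)


def c2bat_screen(
    split: ContingencySplit,
    rng: np.random.Generator | None = None,
    mode: str = "impute",
) -> float:
    """Screening score: |trend Z| of screening table + null-imputed testing cells.

    ``mode='impute'`` draws margin-exact cells under the null;
    ``mode='expected'`` uses the deterministic expected counts (testing aid).
    Degenerate summed tables score 0.
    """
    m = split.testing_col_totals
    a_tot = int(split.testing_a.sum())
    if mode == "impute":
        rng = np.random.default_rng() if rng is None else rng
        imp_a = _impute_affected(rng, m, np.asarray(a_tot))
    elif mode == "expected":
        tot = m.sum()
        imp_a = a_tot * m / tot if tot > 0 else np.zeros(3)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    a_sum = split.screening_a + imp_a
    u_sum = split.screening_u + (m - imp_a)
    U, V = _trend_uv(a_sum, u_sum, (0.0, 1.0, 2.0), "binomial")
    if not V > 0:
        return 0.0
    return float(abs(U) / np.sqrt(V))


def c2bat_test(split: ContingencySplit, variance: str = "binomial"):
    """Two-sided trend test on the testing table only (orthogonal to the screen)."""
    if split.testing_a.sum() + split.testing_u.sum() == 0:
        raise ValueError("empty testing table")
    return trend_test(split.testing_table(), variance=variance)


def c2bat_scan(
    calls: np.ndarray,
    phenotype: np.ndarray,
    fractions=DEFAULT_FRACTIONS,
    rng: np.random.Generator | None = None,
    pos: np.ndarray | None = None,
    snp_ids: np.ndarray | None = None,
) -> ScreenScan:
    """Vectorized screen + test over all SNPs of a case-control calls matrix.

    Works at contingency-table resolution: within genotype class j the number
    of affected subjects entering the testing table is hypergeometric given
    the class's case/control counts, which is distributionally identical to
    sampling subject identities.  Returns a ScreenScan whose ``extras`` carry
    the testing-table trend results (``p_test``, ``z_test``) and the split
    counts.
    """
    rng = np.random.default_rng() if rng is None else rng
    calls = np.asarray(calls)
    phenotype = np.asarray(phenotype)
    fr = np.asarray(fractions, dtype=float)[::-1]  # class order 0,1,2

    use = (phenotype == 0) | (phenotype == 1)
    sub = calls[:, use]
    y = phenotype[use]
    obs = sub >= 0
    a_full = np.stack([((sub == g) & obs & (y == 1)).sum(axis=1) for g in range(3)], axis=-1)
    u_full = np.stack([((sub == g) & obs & (y == 0)).sum(axis=1) for g in range(3)], axis=-1)

    n_class = a_full + u_full
    m = _round_half_away(fr[None, :] * n_class)
    test_a = _safe_hypergeometric(rng, a_full, u_full, m)
    test_u = m - test_a
    scr_a = a_full - test_a
    scr_u = u_full - test_u

    # orthogonal test on the real testing table
    U_t, V_t = _trend_uv(test_a, test_u, (0.0, 1.0, 2.0), "binomial")
    with np.errstate(invalid="ignore", divide="ignore"):
        z_test = np.where(V_t > 0, U_t / np.sqrt(V_t), np.nan)
    p_test = np.where(np.isfinite(z_test), 2.0 * stats.norm.sf(np.abs(z_test)), np.nan)

    # screen on screening table + margin-constrained null imputation
    imp_a = _impute_affected(rng, m, test_a.sum(axis=-1))
    a_sum = scr_a + imp_a
    u_sum = scr_u + (m - imp_a)
    U_s, V_s = _trend_uv(a_sum, u_sum, (0.0, 1.0, 2.0), "binomial")
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(V_s > 0, np.abs(U_s) / np.sqrt(V_s), 0.0)
    degenerate = ~(V_s > 0)

    n_snps = calls.shape[0]
    if pos is None:
        pos = np.arange(n_snps)
    if snp_ids is None:
        snp_ids = np.array([f"snp{i}" for i in range(n_snps)], dtype=object)
    rank = _rank_descending(score, degenerate, pos, snp_ids)
    return ScreenScan(
        snp_ids=np.asarray(snp_ids, dtype=object),
        score=score,
        rank=rank,
        degenerate=degenerate,
        extras={
            "p_test": p_test,
            "z_test": z_test,
            "testing_a": test_a,
            "testing_u": test_u,
            "screening_a": scr_a,
            "screening_u": scr_u,
        },
    )
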