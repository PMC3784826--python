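"""Case-control association statistics: trend test and its stratified version.

The trend test assumes an additive genetic model (scores 0/1/2).  The
stratum-combined version pools the per-stratum score numerators and variances
in the usual Mantel-Haenszel fashion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_data import GenotypeMatrix, PedigreeTable, TrioSet

DEFAULT_SCORES = (0.0, 1.0, 2.0)


@dataclass
class GenotypeCountTable:
    """2x3 affection-by-genotype table: a_j affected, u_j unaffected, j in {0,1,2}."""

    a: np.ndarray
    u: np.ndarray
    stratum: str = "0"

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.int64)
        self.u = np.asarray(self.u, dtype=np.int64)
        if self.a.shape != (3,) or self.u.shape != (3,):
            raise ValueError("count table needs exactly three genotype classes")
        if np.any(self.a < 0) or np.any(self.u < 0):
            raise ValueError("negative cell count")
        if self.total == 0:
            raise ValueError("empty count table")

    @property
    def total(self) -> int:
        return int(self.a.sum() + self.u.sum())

    @classmethod
    def from_genotypes(
        cls, calls: np.ndarray, phenotype: np.ndarray, stratum: str = "0"
    ) -> "GenotypeCountTable":
        """Tabulate one SNP's calls against a 0/1 phenotype, skipping missing."""
        ok = (calls >= 0) & ((phenotype == 0) | (phenotype == 1))
        g = calls[ok]
        y = phenotype[ok]
        a = np.bincount(g[y == 1], minlength=3)[:3]
        u = np.bincount(g[y == 0], minlength=3)[:3]
        return cls(a=a, u=u, stratum=stratum)


@dataclass
class TrendResult:
    U: float
    V: float
    Z: float
    p: float
    testable: bool


def _trend_uv(
    a: np.ndarray, u: np.ndarray, scores, variance: str
) -> tuple[np.ndarray, np.ndarray]:
    """Score numerator U and null variance V, vectorized over leading axes.

    ``a``/``u`` have shape (..., 3).  ``variance`` selects the N^2 binomial
    denominator (default) or the hypergeometric N^2(N-1)/N correction.
    """
    s = np.asarray(scores, dtype=float)
    a = np.asarray(a, dtype=float)
    u = np.asarray(u, dtype=float)
    n_j = a + u
    A = a.sum(axis=-1)
    N = n_j.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        U = (s * (a - n_j * (A / N)[..., None])).sum(axis=-1)
        V = (A * (N - A) / N**2) * ((s**2 * n_j).sum(axis=-1) - (s * n_j).sum(axis=-1) ** 2 / N)
        if variance == "hypergeometric":
            V = V * N / np.maximum(N - 1, 1)
        elif variance != "binomial":
            raise ValueError(f"unknown variance mode {variance!r}")
    return U, V


def trend_test(
    table: GenotypeCountTable,
    scores=DEFAULT_SCORES,
    variance: str = "binomial",
) -> TrendResult:
    """Cochran-Armitage test for trend on a 2x3 table.

    Returns the signed score numerator U, its null variance V, the standard
    score Z = U/sqrt(V) and a two-sided normal p-value.  Degenerate tables
    (V = 0: monomorphic genotype column or a single phenotype class) yield
    ``testable=False`` with NaN Z/p rather than an exception.
    """
    if table.total < 2:
        raise ValueError("trend test requires N >= 2")
    U, V = _trend_uv(table.a, table.u, scores, variance)
    U, V = float(U), float(V)
    if V <= 0:
        return TrendResult(U=U, V=V, Z=np.nan, p=np.nan, testable=False)
    Z = U / np.sqrt(V)
    return TrendResult(U=U, V=V, Z=Z, p=2.0 * stats.norm.sf(abs(Z)), testable=True)


def trend_permutation_p(
    table: GenotypeCountTable, n_perm: int = 100_000, rng: np.random.Generator | None = None
) -> float:
    """Monte-Carlo two-sided p by permuting case/control labels.  Test oracle."""
    rng = np.random.default_rng(0) if rng is None else rng
    obs = trend_test(table)
    if not obs.testable:
        return np.nan
    g = np.repeat([0, 1, 2], (table.a + table.u))
    A = int(table.a.sum())
    s = g.astype(float)
    ref = abs(obs.U)
    hits = 0
    tot_mean = s.mean()
    for _ in range(n_perm):
        pick = rng.permutation(len(g))[:A]
        u_perm = s[pick].sum() - A * tot_mean
        if abs(u_perm) >= ref - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def cmh_trend(
    tables: list[GenotypeCountTable],
    scores=DEFAULT_SCORES,
    variance: str = "binomial",
) -> TrendResult:
    """Stratum-combined trend test: Z = sum(U_k) / sqrt(sum(V_k)).

    Strata with V_k = 0 contribute nothing.  All-degenerate input yields an
    untestable result.
    """
    if not tables:
        raise ValueError("cmh_trend requires at least one stratum")
    U_tot = V_tot = 0.0
    for t in tables:
        U, V = _trend_uv(t.a, t.u, scores, variance)
        if V > 0:
            U_tot += float(U)
            V_tot += float(V)
    if V_tot <= 0:
        return TrendResult(U=U_tot, V=V_tot, Z=np.nan, p=np.nan, testable=False)
    Z = U_tot / np.sqrt(V_tot)
    return TrendResult(U=U_tot, V=V_tot, Z=Z, p=2.0 * stats.norm.sf(abs(Z)), testable=True)


# ---------------------------------------------------------------------------
# Vectorized scan


def trend_scan(
    calls: np.ndarray,
    phenotype: np.ndarray,
    strata: np.ndarray | None = None,
    scores=DEFAULT_SCORES,
    variance: str = "binomial",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP stratified trend test over a calls matrix.

    ``calls`` is (n_snps, n_subjects) with -1 missing; ``phenotype`` 0/1 per
    subject (other codes excluded); ``strata`` optional labels.  Returns
    (Z, p) arrays with NaN where untestable.
    """
    calls = np.asarray(calls)
    phenotype = np.asarray(phenotype)
    use = (phenotype == 0) | (phenotype == 1)
    if strata is None:
        strata = np.zeros(len(phenotype), dtype=np.int64)
    else:
        _, strata = np.unique(np.asarray(strata, dtype=object), return_inverse=True)

    n_snps = calls.shape[0]
    U_tot = np.zeros(n_snps)
    V_tot = np.zeros(n_snps)
    for k in np.unique(strata[use]):
        sel = use & (strata == k)
        sub = calls[:, sel]
        y = phenotype[sel]
        obs = sub >= 0
        # per-SNP 2x3 counts within this stratum
        a = np.stack([((sub == g) & obs & (y == 1)).sum(axis=1) for g in range(3)], axis=-1)
        u = np.stack([((sub == g) & obs & (y == 0)).sum(axis=1) for g in range(3)], axis=-1)
        N = a.sum(axis=-1) + u.sum(axis=-1)
        ok = N > 0
        U = np.zeros(n_snps)
        V = np.zeros(n_snps)
        U[ok], V[ok] = _trend_uv(a[ok], u[ok], scores, variance)
        pos = V > 0
        U_tot[pos] += U[pos]
        V_tot[pos] += V[pos]

    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(V_tot > 0, U_tot / np.sqrt(V_tot), np.nan)
    p = np.where(np.isfinite(Z), 2.0 * stats.norm.sf(np.abs(Z)), np.nan)
    return Z, p


def singleton_association(
    genotypes: GenotypeMatrix,
    pedigree: PedigreeTable,
    trios: TrioSet,
    subset: str = "singletons_only",
    variance: str = "binomial",
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified trend scan over the unrelated subset.

    ``subset`` is either ``singletons_only`` or ``pooled_with_probands``; the
    pooled mode adds trio offspring (with their phenotypes) to the unrelated
    set, replicating the single-step pooled strategy.  Returns (Z, p).
    """
    if subset == "singletons_only":
        idx = trios.singleton_idx
    elif subset == "pooled_with_probands":
        idx = np.concatenate([trios.singleton_idx, trios.offspring_idx])
    else:
        raise ValueError(f"unknown subset {subset!r}")
    if idx.size == 0:
        raise ValueError("empty case-control subset")
    return trend_scan(
        genotypes.calls[:, idx],
        pedigree.phenotype[idx],
        strata=pedigree.stratum[idx],
        variance=variance,
    )
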