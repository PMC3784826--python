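"""Mendelian transmission model and the offset-weighted trio association test.

Each trio contributes T_i * (X_i - E[X_i | parents]) to the numerator, where
T_i = Y_i - offset recodes the binary phenotype around the trait prevalence.
With offset 0 the statistic reduces to an affecteds-only transmission test;
a positive offset lets unaffected offspring contribute with negative weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_data import GenotypeMatrix, TrioSet

DEFAULT_OFFSET = 0.3
MIN_INFORMATIVE = 10


@dataclass
class TransmissionDistribution:
    """Offspring minor-allele-count distribution given ordered parental scores."""

    probs: np.ndarray  # P(X = 0, 1, 2 | parents)
    mean: float
    var: float

    def __post_init__(self) -> None:
        if not np.isclose(self.probs.sum(), 1.0):
            raise ValueError("transmission probabilities must sum to 1")
        if not 0.0 <= self.mean <= 2.0 or self.var < 0:
            raise ValueError("invalid transmission moments")


@dataclass
class FbatResult:
    U: float
    V: float
    Z: float
    p: float
    n_informative: int
    testable: bool
    low_info: bool = False


def offspring_distribution(father_score: int, mother_score: int) -> TransmissionDistribution:
    """Exact Mendelian offspring distribution for parental scores in {0,1,2}.

    Each parent independently transmits the counted allele with probability
    score/2, so X is the sum of two Bernoulli draws.
    """
    for s in (father_score, mother_score):
        if s not in (0, 1, 2):
            raise ValueError(f"parental score must be 0, 1 or 2 (got {s})")
    pf = father_score / 2.0
    pm = mother_score / 2.0
    probs = np.array(
        [
            (1 - pf) * (1 - pm),
            pf * (1 - pm) + (1 - pf) * pm,
            pf * pm,
        ]
    )
    mean = pf + pm
    var = pf * (1 - pf) + pm * (1 - pm)
    return TransmissionDistribution(probs=probs, mean=mean, var=var)


def _transmission_moments(f: np.ndarray, m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """E[X|parents] and Var[X|parents], elementwise over score arrays."""
    pf = f / 2.0
    pm = m / 2.0
    return pf + pm, pf * (1 - pf) + pm * (1 - pm)


def fbat_test(
    snp: int,
    trios: TrioSet,
    genotypes: GenotypeMatrix,
    offset: float = DEFAULT_OFFSET,
    min_informative: int = MIN_INFORMATIVE,
) -> FbatResult:
    """Offset-weighted transmission test at one SNP.

    U = sum_i T_i (X_i - E[X_i|S_i]),  V = sum_i T_i^2 Var[X_i|S_i],
    Z = U/sqrt(V), two-sided normal p.  Trios with any missing call are
    skipped; V = 0 flags the SNP untestable.
    """
    if trios.n_trios == 0:
        raise ValueError("fbat_test requires at least one trio")
    row = genotypes.calls[snp]
    u, v, n_inf = _fbat_uv(
        row[trios.father_idx][None, :],
        row[trios.mother_idx][None, :],
        row[trios.offspring_idx][None, :],
        trios.offspring_phenotype.astype(float) - offset,
    )
    U, V, n_inf = float(u[0]), float(v[0]), int(n_inf[0])
    if V <= 0:
        return FbatResult(U=U, V=V, Z=np.nan, p=np.nan, n_informative=n_inf, testable=False)
    Z = U / np.sqrt(V)
    return FbatResult(
        U=U,
        V=V,
        Z=Z,
        p=2.0 * stats.norm.sf(abs(Z)),
        n_informative=n_inf,
        testable=True,
        low_info=n_inf < min_informative,
    )


def _fbat_uv(
    f: np.ndarray, m: np.ndarray, x: np.ndarray, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized numerator/variance over (n_snps, n_trios) score arrays.

    ``t`` is the per-trio phenotype weight Y - offset.  Missing calls in any
    trio member drop that trio for the SNP.  Returns (U, V, n_informative).
    """
    ok = (f >= 0) & (m >= 0) & (x >= 0)
    e, var = _transmission_moments(
        np.where(ok, f, 0).astype(float), np.where(ok, m, 0).astype(float)
    )
    w = np.where(ok, t[None, :], 0.0)
    U = (w * (np.where(ok, x, 0) - e)).sum(axis=1)
    V = (w**2 * var).sum(axis=1)
    n_inf = ((var > 0) & ok & (w != 0)).sum(axis=1)
    return U, V, n_inf


def fbat_scan(
    trios: TrioSet,
    genotypes: GenotypeMatrix,
    offset: float = DEFAULT_OFFSET,
    min_informative: int = MIN_INFORMATIVE,
) -> dict[str, np.ndarray]:
    """Apply the trio test across all SNPs; untestable rows kept with NaN p."""
    if trios.n_trios == 0:
        raise ValueError("fbat_scan requires at least one trio")
    t = trios.offspring_phenotype.astype(float) - offset
    U, V, n_inf = _fbat_uv(
        genotypes.calls[:, trios.father_idx],
        genotypes.calls[:, trios.mother_idx],
        genotypes.calls[:, trios.offspring_idx],
        t,
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(V > 0, U / np.sqrt(V), np.nan)
    p = np.where(np.isfinite(Z), 2.0 * stats.norm.sf(np.abs(Z)), np.nan)
    return {
        "U": U,
        "V": V,
        "Z": Z,
        "p": p,
        "n_informative": n_inf,
        "testable": V > 0,
        "low_info": n_inf < min_informative,
    }
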