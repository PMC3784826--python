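import numpy as np
import pytest

from famcc.core_data import GenotypeMatrix, PedigreeTable, TrioSet, build_trios
from famcc.simulate import SimulationConfig, simulate_cohort


def make_genotypes(calls, pos=None, snp_ids=None, subject_ids=None):
    """GenotypeMatrix from a raw int array, ids autogenerated."""
    calls = np.asarray(calls, dtype=np.int8)
    n_snps, n_sub = calls.shape
    return GenotypeMatrix(
        snp_ids=np.array(snp_ids if snp_ids is not None else [f"s{i}" for i in range(n_snps)], dtype=object),
        chrom=np.full(n_snps, "1", dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, n_snps + 1) * 100, dtype=np.int64),
        subject_ids=np.array(
            subject_ids if subject_ids is not None else [f"i{i}" for i in range(n_sub)], dtype=object
        ),
        calls=calls,
    )


def make_trios(n, phenotypes):
    """TrioSet over subjects laid out F0,M0,C0,F1,M1,C1,..."""
    base = np.arange(n) * 3
    return TrioSet(
        father_idx=base,
        mother_idx=base + 1,
        offspring_idx=base + 2,
        offspring_phenotype=np.asarray(phenotypes, dtype=np.int8),
    )


def make_pedigree(rows):
    """rows: list of (fam, iid, fid, mid, sex, stratum, phenotype)."""
    cols = list(zip(*rows))
    return PedigreeTable(
        family_id=np.array(cols[0], dtype=object),
        individual_id=np.array(cols[1], dtype=object),
        father_id=np.array(cols[2], dtype=object),
        mother_id=np.array(cols[3], dtype=object),
        sex=np.array(cols[4], dtype=np.int64),
        stratum=np.array(cols[5], dtype=object),
        phenotype=np.array(cols[6], dtype=np.int8),
    )


@pytest.fixture(scope="session")
def small_study():
    cfg = SimulationConfig(
        n_snps=300, n_trios=120, n_cases=150, n_controls=150, seed=12
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_trios(small_study):
    return build_trios(small_study.pedigree)
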