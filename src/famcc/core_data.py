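"""Data model, PED/MAP I/O, trio assembly, and marker quality control.

Genotypes are held SNP-major as minor-allele counts in ``{0, 1, 2}`` with
``-1`` marking a missing call.  Subject order follows the PED file, SNP order
follows the MAP file, and both orders are preserved by every operation here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_CALL = np.int8(-1)
MISSING_PHENO = np.int8(-9)
MISSING_PARENT = "0"

QC_REASONS = ("mendel", "call_rate", "maf", "monomorphic")


@dataclass
class PedigreeTable:
    """Per-subject family structure, sex, stratum and binary phenotype.

    ``phenotype`` is coded 1 = affected, 0 = unaffected, -9 = missing
    (PED column six 2/1/0 is remapped on input).  ``stratum`` is a free-text
    label used for stratified testing; a single shared label means an
    unstratified analysis.
    """

    family_id: np.ndarray
    individual_id: np.ndarray
    father_id: np.ndarray
    mother_id: np.ndarray
    sex: np.ndarray  # PLINK codes: 1 male, 2 female, 0 unknown
    stratum: np.ndarray
    phenotype: np.ndarray  # int8 in {1, 0, -9}

    def __post_init__(self) -> None:
        n = len(self.individual_id)
        for name in ("family_id", "father_id", "mother_id", "sex", "stratum", "phenotype"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"pedigree column {name!r} length mismatch")
        keys = list(zip(self.family_id.tolist(), self.individual_id.tolist()))
        if len(set(keys)) != n:
            raise ValueError("duplicate (family_id, individual_id) pair in pedigree")
        bad = set(np.unique(self.phenotype).tolist()) - {-9, 0, 1}
        if bad:
            raise ValueError(f"invalid phenotype codes: {sorted(bad)}")

    @property
    def n_subjects(self) -> int:
        return len(self.individual_id)

    def subject_index(self) -> dict[tuple[str, str], int]:
        """Map (family_id, individual_id) -> row index."""
        return {
            (f, i): k
            for k, (f, i) in enumerate(zip(self.family_id.tolist(), self.individual_id.tolist()))
        }

    def equals(self, other: "PedigreeTable") -> bool:
        return all(
            np.array_equal(getattr(self, c), getattr(other, c))
            for c in ("family_id", "individual_id", "father_id", "mother_id", "sex", "stratum", "phenotype")
        )


@dataclass
class GenotypeMatrix:
    """SNP x subject minor-allele counts.

    Invariant: after :meth:`orient_minor` the frequency of the counted allele
    is at most 0.5 at every SNP (computed over non-missing calls).
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    subject_ids: np.ndarray
    calls: np.ndarray  # int8, shape (n_snps, n_subjects)
    counted_allele: np.ndarray | None = None  # minor allele letter; "" if never observed
    other_allele: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.snp_ids), len(self.subject_ids)):
            raise ValueError("calls shape does not match id lists")
        if self.counted_allele is None:
            self.counted_allele = np.full(len(self.snp_ids), "A", dtype=object)
        if self.other_allele is None:
            self.other_allele = np.full(len(self.snp_ids), "B", dtype=object)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def maf(self) -> np.ndarray:
        """Counted-allele frequency per SNP over non-missing calls (NaN if all missing)."""
        obs = self.calls >= 0
        n_obs = obs.sum(axis=1)
        tot = np.where(obs, self.calls, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, tot / (2.0 * n_obs), np.nan)

    def call_rate(self) -> np.ndarray:
        return (self.calls >= 0).mean(axis=1)

    def orient_minor(self) -> "GenotypeMatrix":
        """Flip SNPs so the counted allele is the minor one.  Idempotent."""
        freq = self.maf()
        flip = freq > 0.5
        calls = self.calls.copy()
        calls[flip] = np.where(calls[flip] >= 0, 2 - calls[flip], MISSING_CALL).astype(np.int8)
        counted = self.counted_allele.copy()
        other = self.other_allele.copy()
        counted[flip], other[flip] = other[flip].copy(), counted[flip].copy()
        return replace(self, calls=calls, counted_allele=counted, other_allele=other)

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            snp_ids=self.snp_ids[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            subject_ids=self.subject_ids,
            calls=self.calls[idx],
            counted_allele=self.counted_allele[idx],
            other_allele=self.other_allele[idx],
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.snp_ids, other.snp_ids)
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.subject_ids, other.subject_ids)
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class TrioSet:
    """Complete mother-father-offspring units indexed into subject order."""

    father_idx: np.ndarray
    mother_idx: np.ndarray
    offspring_idx: np.ndarray
    offspring_phenotype: np.ndarray  # int8 in {0, 1}
    singleton_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))

    def __post_init__(self) -> None:
        members = np.concatenate([self.father_idx, self.mother_idx, self.offspring_idx])
        if len(np.unique(members)) != len(members):
            raise ValueError("a subject appears in more than one trio role")
        if np.any((self.offspring_phenotype != 0) & (self.offspring_phenotype != 1)):
            raise ValueError("trio offspring phenotype must be 0/1")

    @property
    def n_trios(self) -> int:
        return len(self.offspring_idx)


@dataclass
class QcReport:
    """Per-SNP QC metrics plus the removal decision and its reason code."""

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    maf: np.ndarray
    call_rate: np.ndarray
    mendel_trios: np.ndarray
    removed: np.ndarray  # bool
    reason: np.ndarray  # "" or one of QC_REASONS

    def __post_init__(self) -> None:
        bad = set(np.unique(self.reason).tolist()) - ({""} | set(QC_REASONS))
        if bad:
            raise ValueError(f"invalid QC reason codes: {sorted(bad)}")
        if np.any(self.mendel_trios < 0):
            raise ValueError("negative Mendelian-error count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "chr": self.chrom,
                "bp": self.pos,
                "maf": self.maf,
                "call_rate": self.call_rate,
                "mendel_trios": self.mendel_trios,
                "removed": self.removed.astype(int),
                "reason": self.reason,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PED/MAP I/O


def _read_map(map_path) -> pd.DataFrame:
    mp = pd.read_csv(map_path, sep=r"\s+", header=None, dtype=str, comment="#")
    if mp.shape[1] == 4:
        mp.columns = ["chr", "snp_id", "cm", "bp"]
    elif mp.shape[1] == 3:
        mp.columns = ["chr", "snp_id", "bp"]
    else:
        raise ValueError(f"MAP file must have 3 or 4 columns, found {mp.shape[1]}")
    mp["bp"] = mp["bp"].astype(np.int64)
    return mp


def read_ped(ped_path, map_path, pheno_path=None) -> tuple[PedigreeTable, GenotypeMatrix]:
    """Parse whitespace-delimited PED/MAP into pedigree + oriented genotypes.

    PED layout: six leading columns (family, individual, father, mother, sex,
    phenotype) then two allele columns per MAP SNP.  Allele code "0" means
    missing; any pair containing it becomes a missing call.  Genotypes are
    oriented so the counted allele is the minor one.

    An optional phenotype/stratum TSV (columns ``subject_id``, ``phenotype``,
    ``stratum``) overrides PED column six and supplies stratum labels.
    """
    mp = _read_map(map_path)
    n_snps = len(mp)

    ped = pd.read_csv(ped_path, sep=r"\s+", header=None, dtype=str)
    expected_cols = 6 + 2 * n_snps
    if ped.shape[1] != expected_cols:
        raise ValueError(
            f"PED has {ped.shape[1]} columns but MAP implies {expected_cols} "
            f"(6 + 2 x {n_snps} SNPs); first offending line is line 1"
        )

    fam = ped.iloc[:, 0].to_numpy(dtype=object)
    iid = ped.iloc[:, 1].to_numpy(dtype=object)
    if len(set(zip(fam.tolist(), iid.tolist()))) != len(iid):
        raise ValueError("duplicate subject id (family_id, individual_id) in PED")

    pheno_raw = ped.iloc[:, 5].to_numpy(dtype=object)
    phenotype = np.full(len(iid), MISSING_PHENO, dtype=np.int8)
    phenotype[pheno_raw == "2"] = 1
    phenotype[pheno_raw == "1"] = 0

    stratum = np.full(len(iid), "0", dtype=object)
    if pheno_path is not None:
        cov = pd.read_csv(pheno_path, sep="\t", dtype=str)
        cov_map = cov.set_index("subject_id")
        for k, sid in enumerate(iid):
            if sid in cov_map.index:
                row = cov_map.loc[sid]
                if "phenotype" in cov.columns and not pd.isna(row["phenotype"]):
                    phenotype[k] = np.int8(int(row["phenotype"]))
                if "stratum" in cov.columns and not pd.isna(row["stratum"]):
                    stratum[k] = row["stratum"]

    pedigree = PedigreeTable(
        family_id=fam,
        individual_id=iid,
        father_id=ped.iloc[:, 2].to_numpy(dtype=object),
        mother_id=ped.iloc[:, 3].to_numpy(dtype=object),
        sex=ped.iloc[:, 4].astype(int).to_numpy(),
        stratum=stratum,
        phenotype=phenotype,
    )

    allele_block = ped.iloc[:, 6:].to_numpy(dtype=object)
    calls = np.empty((n_snps, len(iid)), dtype=np.int8)
    counted = np.empty(n_snps, dtype=object)
    other = np.empty(n_snps, dtype=object)
    for j in range(n_snps):
        a1 = allele_block[:, 2 * j]
        a2 = allele_block[:, 2 * j + 1]
        missing = (a1 == "0") | (a2 == "0")
        seen = sorted(set(a1[~missing].tolist()) | set(a2[~missing].tolist()))
        if len(seen) > 2:
            raise ValueError(f"SNP {mp['snp_id'][j]} has more than two alleles: {seen}")
        if len(seen) == 0:
            counted[j], other[j] = "", ""
            calls[j] = MISSING_CALL
            continue
        if len(seen) == 1:
            # one allele observed: the counted (minor) allele is the absent one
            counted[j], other[j] = "", seen[0]
            calls[j] = np.where(missing, MISSING_CALL, 0).astype(np.int8)
            continue
        lo, hi = seen  # lexicographic; orientation fixed below
        cnt = (a1 == lo).astype(np.int8) + (a2 == lo).astype(np.int8)
        calls[j] = np.where(missing, MISSING_CALL, cnt).astype(np.int8)
        counted[j], other[j] = lo, hi

    geno = GenotypeMatrix(
        snp_ids=mp["snp_id"].to_numpy(dtype=object),
        chrom=mp["chr"].to_numpy(dtype=object),
        pos=mp["bp"].to_numpy(),
        subject_ids=iid,
        calls=calls,
        counted_allele=counted,
        other_allele=other,
    ).orient_minor()
    return pedigree, geno


def write_ped(pedigree: PedigreeTable, genotypes: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PED/MAP that :func:`read_ped` round-trips to identical objects."""
    with open(map_path, "w") as fh:
        for c, s, b in zip(genotypes.chrom, genotypes.snp_ids, genotypes.pos):
            fh.write(f"{c}\t{s}\t0\t{b}\n")

    pheno_out = np.full(pedigree.n_subjects, "0", dtype=object)
    pheno_out[pedigree.phenotype == 1] = "2"
    pheno_out[pedigree.phenotype == 0] = "1"

    minor = np.where(genotypes.counted_allele == "", "?", genotypes.counted_allele)
    major = genotypes.other_allele
    with open(ped_path, "w") as fh:
        for i in range(pedigree.n_subjects):
            lead = [
                pedigree.family_id[i],
                pedigree.individual_id[i],
                pedigree.father_id[i],
                pedigree.mother_id[i],
                str(int(pedigree.sex[i])),
                pheno_out[i],
            ]
            col = genotypes.calls[:, i]
            pairs = []
            for j, g in enumerate(col):
                if g < 0:
                    pairs.append("0 0")
                elif g == 0:
                    pairs.append(f"{major[j]} {major[j]}")
                elif g == 1:
                    pairs.append(f"{minor[j]} {major[j]}")
                else:
                    pairs.append(f"{minor[j]} {minor[j]}")
            fh.write(" ".join(lead) + " " + " ".join(pairs) + "\n")


# ---------------------------------------------------------------------------
# Trio assembly


def build_trios(pedigree: PedigreeTable) -> TrioSet:
    """Assemble complete mother-father-offspring trios.

    Offspring with exactly one resolvable parent are excluded from both the
    trio set and the singleton complement.  One offspring per family (lowest
    individual_id).  Singletons are subjects with both parent fields missing
    that do not serve as a parent in any assembled trio.
    """
    idx = pedigree.subject_index()
    has_father = pedigree.father_id != MISSING_PARENT
    has_mother = pedigree.mother_id != MISSING_PARENT

    candidates: dict[str, list[int]] = {}
    for i in range(pedigree.n_subjects):
        if not (has_father[i] and has_mother[i]):
            continue
        fam = pedigree.family_id[i]
        f_key = (fam, pedigree.father_id[i])
        m_key = (fam, pedigree.mother_id[i])
        if f_key not in idx or m_key not in idx:
            logger.warning(
                "family %s: offspring %s references absent parent; family excluded",
                fam, pedigree.individual_id[i],
            )
            continue
        if pedigree.phenotype[i] == MISSING_PHENO:
            continue
        candidates.setdefault(fam, []).append(i)

    first_seen: dict[str, int] = {}
    for i, fam in enumerate(pedigree.family_id):
        first_seen.setdefault(fam, i)
    fathers, mothers, kids = [], [], []
    for fam in sorted(candidates, key=first_seen.__getitem__):
        rows = sorted(candidates[fam], key=lambda i: pedigree.individual_id[i])
        i = rows[0]  # lowest individual_id wins when sibs share parents
        fathers.append(idx[(fam, pedigree.father_id[i])])
        mothers.append(idx[(fam, pedigree.mother_id[i])])
        kids.append(i)

    in_trio = np.zeros(pedigree.n_subjects, dtype=bool)
    in_trio[fathers] = True
    in_trio[mothers] = True
    in_trio[kids] = True
    singleton = ~in_trio & ~has_father & ~has_mother
    # parents of excluded/partial families are not singletons either
    referenced = set()
    for i in range(pedigree.n_subjects):
        fam = pedigree.family_id[i]
        for pid in (pedigree.father_id[i], pedigree.mother_id[i]):
            if pid != MISSING_PARENT and (fam, pid) in idx:
                referenced.add(idx[(fam, pid)])
    for r in referenced:
        if not in_trio[r]:
            singleton[r] = False

    return TrioSet(
        father_idx=np.asarray(fathers, dtype=np.intp),
        mother_idx=np.asarray(mothers, dtype=np.intp),
        offspring_idx=np.asarray(kids, dtype=np.intp),
        offspring_phenotype=pedigree.phenotype[kids].astype(np.int8)
        if kids
        else np.empty(0, dtype=np.int8),
        singleton_idx=np.flatnonzero(singleton),
    )


# ---------------------------------------------------------------------------
# Mendelian consistency


def _mendel_error_mask(f: np.ndarray, m: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Boolean mask of trios whose offspring call is impossible given parents.

    A parent with call 0 can only transmit the major allele, a parent with
    call 2 only the minor one, so the offspring count must lie in
    ``[(f==2)+(m==2), (f>0)+(m>0)]``.  Trios with any missing call are never
    flagged.
    """
    complete = (f >= 0) & (m >= 0) & (x >= 0)
    lo = (f == 2).astype(np.int8) + (m == 2).astype(np.int8)
    hi = (f > 0).astype(np.int8) + (m > 0).astype(np.int8)
    return complete & ((x < lo) | (x > hi))


def mendel_error_trios(snp: int, trios: TrioSet, genotypes: GenotypeMatrix) -> int:
    """Count trios inconsistent with Mendelian transmission at one SNP."""
    row = genotypes.calls[snp]
    return int(
        _mendel_error_mask(
            row[trios.father_idx], row[trios.mother_idx], row[trios.offspring_idx]
        ).sum()
    )


def mendel_error_counts(trios: TrioSet, genotypes: GenotypeMatrix) -> np.ndarray:
    """Vectorized per-SNP Mendelian-error trio counts."""
    if trios.n_trios == 0:
        return np.zeros(genotypes.n_snps, dtype=np.int64)
    f = genotypes.calls[:, trios.father_idx]
    m = genotypes.calls[:, trios.mother_idx]
    x = genotypes.calls[:, trios.offspring_idx]
    return _mendel_error_mask(f, m, x).sum(axis=1)


# ---------------------------------------------------------------------------
# QC filter


def filter_snps(
    genotypes: GenotypeMatrix,
    trios: TrioSet | None = None,
    max_mendel_trios: int = 2,
    min_call_rate: float = 0.95,
    min_maf: float = 0.01,
    subjects: np.ndarray | None = None,
    zero_mendel_errors: bool = True,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs failing Mendelian, call-rate, MAF or monomorphism checks.

    A SNP is dropped when more than ``max_mendel_trios`` trios show a
    Mendelian error (default 2, i.e. removal at 3 or more), when its call
    rate over ``subjects`` (default: everyone) falls below ``min_call_rate``,
    when its MAF falls below ``min_maf``, or when it is monomorphic.
    Surviving SNPs keep their original order.  At retained SNPs, members of
    trios exhibiting a Mendelian error are set missing for that SNP only
    (disable via ``zero_mendel_errors``).
    """
    sub = np.arange(genotypes.n_subjects) if subjects is None else np.asarray(subjects)
    calls_sub = genotypes.calls[:, sub]
    obs = calls_sub >= 0
    n_obs = obs.sum(axis=1)
    call_rate = n_obs / max(len(sub), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(n_obs > 0, np.where(obs, calls_sub, 0).sum(axis=1) / (2.0 * n_obs), 0.0)
    maf = np.minimum(maf, 1.0 - maf)

    mendel = (
        mendel_error_counts(trios, genotypes)
        if trios is not None and trios.n_trios > 0
        else np.zeros(genotypes.n_snps, dtype=np.int64)
    )

    reason = np.full(genotypes.n_snps, "", dtype=object)
    # precedence: mendel > call_rate > maf > monomorphic
    mono = maf <= 0.0
    reason[mono] = "monomorphic"
    reason[maf < min_maf] = np.where(mono[maf < min_maf], "monomorphic", "maf")
    reason[call_rate < min_call_rate] = "call_rate"
    reason[mendel > max_mendel_trios] = "mendel"
    removed = reason != ""

    report = QcReport(
        snp_ids=genotypes.snp_ids,
        chrom=genotypes.chrom,
        pos=genotypes.pos,
        maf=maf,
        call_rate=call_rate,
        mendel_trios=mendel,
        removed=removed,
        reason=reason,
    )

    keep = np.flatnonzero(~removed)
    if keep.size == 0:
        raise RuntimeError("no SNPs pass QC")
    kept = genotypes.take_snps(keep)

    if zero_mendel_errors and trios is not None and trios.n_trios > 0:
        f = kept.calls[:, trios.father_idx]
        m = kept.calls[:, trios.mother_idx]
        x = kept.calls[:, trios.offspring_idx]
        bad = _mendel_error_mask(f, m, x)
        if bad.any():
            calls = kept.calls.copy()
            snp_i, trio_i = np.nonzero(bad)
            for member in (trios.father_idx, trios.mother_idx, trios.offspring_idx):
                calls[snp_i, member[trio_i]] = MISSING_CALL
            kept = replace(kept, calls=calls)

    return kept, report
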