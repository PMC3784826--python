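"""Synthetic mixed-design cohorts: trios plus unrelated cases and controls.

Parents are drawn from Hardy-Weinberg proportions, offspring by Mendelian
transmission, and disease status from a logistic model on the causal minor
allele counts with the intercept calibrated to a target marginal prevalence.
Subjects are ascertained by phenotype to hit the requested case/control and
proband quotas.  An optional two-subpopulation confounder shifts both allele
frequencies and baseline risk.  SNPs are simulated independently (no LD).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .core_data import GenotypeMatrix, PedigreeTable, write_ped

_MAX_DRAWS = 1_000_000


@dataclass
class Stratification:
    """Two-subpopulation confounder: shifts in allele frequency and risk."""

    maf_delta: float = 0.2
    prevalence_delta: float = 0.2
    mixing: float = 0.5  # P(subject from subpopulation 2)


@dataclass
class SimulationConfig:
    n_snps: int
    n_trios: int
    n_cases: int
    n_controls: int
    seed: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_snps: list = field(default_factory=list)  # (index, odds_ratio[, maf])
    prevalence: float = 0.3
    n_case_probands: int | None = None
    stratification: Stratification | None = None
    genotyping_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        for entry in self.causal_snps:
            if not 0 <= entry[0] < self.n_snps:
                raise ValueError(f"causal SNP index {entry[0]} out of range")
            if entry[1] <= 0:
                raise ValueError("odds ratios must be positive")


@dataclass
class SimulatedStudy:
    """A simulated cohort plus ground truth annotations."""

    pedigree: PedigreeTable
    genotypes: GenotypeMatrix
    causal_or: dict[int, float]
    subpop: np.ndarray  # 1 or 2 per subject
    mafs: np.ndarray
    config: SimulationConfig

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.genotypes.snp_ids,
                "maf": self.mafs,
                "causal": [int(i in self.causal_or) for i in range(len(self.mafs))],
                "odds_ratio": [self.causal_or.get(i, 1.0) for i in range(len(self.mafs))],
            }
        )


def _calibrate_intercept(ors: np.ndarray, mafs: np.ndarray, prevalence: float) -> float:
    """Solve the logistic intercept so the marginal prevalence matches.

    Enumerates the joint HWE distribution of the causal genotypes (assumed
    independent); exact to brentq tolerance.
    """
    if len(ors) == 0:
        return float(np.log(prevalence / (1.0 - prevalence)))
    if len(ors) > 10:
        raise ValueError("too many causal SNPs to enumerate jointly")
    log_or = np.log(ors)
    combos = np.array(list(itertools.product((0, 1, 2), repeat=len(ors))), dtype=float)
    hw = np.stack(
        [np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]) for p in mafs]
    )  # (k, 3)
    probs = np.prod(hw[np.arange(len(ors)), combos.astype(int)], axis=1)
    lin = combos @ log_or

    def marginal(b0: float) -> float:
        return float((probs * expit(b0 + lin)).sum()) - prevalence

    return brentq(marginal, -40.0, 40.0, xtol=1e-8)


def _draw_subpop(rng, n, strat: Stratification | None) -> np.ndarray:
    if strat is None:
        return np.ones(n, dtype=np.int8)
    return np.where(rng.random(n) < strat.mixing, 2, 1).astype(np.int8)


class _CohortSampler:
    """Phenotype-first rejection sampler over the causal genotypes only.

    Non-causal SNPs are independent of phenotype given subpopulation, so they
    are filled in after ascertainment — exact and far cheaper than simulating
    every SNP for every rejected candidate.
    """

    def __init__(self, config: SimulationConfig, rng: np.random.Generator, mafs: np.ndarray):
        self.cfg = config
        self.rng = rng
        self.strat = config.stratification
        self.causal_idx = np.array([int(e[0]) for e in config.causal_snps], dtype=int)
        self.ors = np.array([float(e[1]) for e in config.causal_snps])
        self.maf1 = mafs
        if self.strat is not None:
            self.maf2 = np.clip(mafs + self.strat.maf_delta, 0.01, 0.99)
            prev2 = float(np.clip(config.prevalence + self.strat.prevalence_delta, 0.01, 0.99))
        else:
            self.maf2 = mafs
            prev2 = config.prevalence
        c1 = self.maf1[self.causal_idx] if len(self.causal_idx) else np.empty(0)
        c2 = self.maf2[self.causal_idx] if len(self.causal_idx) else np.empty(0)
        self.b0 = {
            1: _calibrate_intercept(self.ors, c1, config.prevalence),
            2: _calibrate_intercept(self.ors, c2, prev2),
        }

    def _causal_maf(self, subpop: np.ndarray) -> np.ndarray:
        """Causal-SNP allele frequencies per subject, shape (n, k)."""
        c1 = self.maf1[self.causal_idx]
        c2 = self.maf2[self.causal_idx]
        return np.where((subpop == 2)[:, None], c2[None, :], c1[None, :])

    def _phenotype(self, g_causal: np.ndarray, subpop: np.ndarray) -> np.ndarray:
        lin = np.array([self.b0[s] for s in (1, 2)])[subpop - 1]
        if len(self.ors):
            lin = lin + g_causal @ np.log(self.ors)
        return (self.rng.random(len(subpop)) < expit(lin)).astype(np.int8)

    def sample_singletons(self, n_cases: int, n_controls: int):
        """Returns (phenotype, subpop, causal genotypes) for ascertained singletons."""
        got_case, got_ctrl = [], []
        drawn = 0
        batch = max(256, 4 * (n_cases + n_controls))
        while len(got_case) < n_cases or len(got_ctrl) < n_controls:
            if drawn > _MAX_DRAWS:
                raise RuntimeError(
                    f"could not ascertain {n_cases}/{n_controls} cases/controls "
                    f"within {_MAX_DRAWS} draws (prevalence too extreme?)"
                )
            sp = _draw_subpop(self.rng, batch, self.strat)
            g = self.rng.binomial(2, self._causal_maf(sp)).astype(np.int8)
            y = self._phenotype(g, sp)
            drawn += batch
            for i in np.flatnonzero(y == 1):
                if len(got_case) < n_cases:
                    got_case.append((sp[i], g[i]))
            for i in np.flatnonzero(y == 0):
                if len(got_ctrl) < n_controls:
                    got_ctrl.append((sp[i], g[i]))
        rows = got_case + got_ctrl
        y = np.array([1] * n_cases + [0] * n_controls, dtype=np.int8)
        sp = np.array([r[0] for r in rows], dtype=np.int8)
        g = (
            np.array([r[1] for r in rows], dtype=np.int8).reshape(len(rows), -1)
            if rows
            else np.empty((0, len(self.causal_idx)), dtype=np.int8)
        )
        return y, sp, g

    def sample_trios(self, n_case_probands: int, n_control_probands: int):
        """Ascertain trios by proband phenotype.

        Returns (proband phenotype, subpop, father/mother/child causal
        genotypes), each genotype array shaped (n_trios, k).
        """
        got_case, got_ctrl = [], []
        drawn = 0
        batch = max(256, 4 * (n_case_probands + n_control_probands))
        while len(got_case) < n_case_probands or len(got_ctrl) < n_control_probands:
            if drawn > _MAX_DRAWS:
                raise RuntimeError(
                    f"could not ascertain {n_case_probands}/{n_control_probands} "
                    f"case/control probands within {_MAX_DRAWS} draws"
                )
            sp = _draw_subpop(self.rng, batch, self.strat)
            pm = self._causal_maf(sp)
            gf = self.rng.binomial(2, pm).astype(np.int8)
            gm = self.rng.binomial(2, pm).astype(np.int8)
            gc = (self.rng.binomial(1, gf / 2.0) + self.rng.binomial(1, gm / 2.0)).astype(np.int8)
            y = self._phenotype(gc, sp)
            drawn += batch
            for i in np.flatnonzero(y == 1):
                if len(got_case) < n_case_probands:
                    got_case.append((sp[i], gf[i], gm[i], gc[i]))
            for i in np.flatnonzero(y == 0):
                if len(got_ctrl) < n_control_probands:
                    got_ctrl.append((sp[i], gf[i], gm[i], gc[i]))
        rows = got_case + got_ctrl
        y = np.array([1] * n_case_probands + [0] * n_control_probands, dtype=np.int8)
        sp = np.array([r[0] for r in rows], dtype=np.int8)
        k = len(self.causal_idx)

        def _stack(pos):
            if not rows:
                return np.empty((0, k), dtype=np.int8)
            return np.array([r[pos] for r in rows], dtype=np.int8).reshape(len(rows), -1)

        return y, sp, _stack(1), _stack(2), _stack(3)

    def fill_noncausal(self, subpop: np.ndarray) -> np.ndarray:
        """HWE genotypes for every SNP x subject; causal columns overwritten later."""
        n = len(subpop)
        out = np.empty((self.cfg.n_snps, n), dtype=np.int8)
        for s, mafs in ((1, self.maf1), (2, self.maf2)):
            cols = np.flatnonzero(subpop == s)
            if cols.size:
                out[:, cols] = self.rng.binomial(
                    2, mafs[:, None], size=(self.cfg.n_snps, cols.size)
                ).astype(np.int8)
        return out

    def transmit(self, father: np.ndarray, mother: np.ndarray) -> np.ndarray:
        """Mendelian offspring calls, elementwise over (n_snps, n_trios)."""
        return (
            self.rng.binomial(1, father / 2.0) + self.rng.binomial(1, mother / 2.0)
        ).astype(np.int8)


def simulate_cohort(config: SimulationConfig) -> SimulatedStudy:
    """Generate a full PED-style cohort per the configuration.

    Subject order: trio families first (father, mother, offspring per
    family), then singleton cases, then singleton controls.  Parents carry a
    missing phenotype; strata default to a single shared label (the true
    subpopulation is recorded separately and never exposed as a stratum).
    """
    rng = np.random.default_rng(config.seed)
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_snps)
    for entry in config.causal_snps:
        if len(entry) > 2 and entry[2] is not None:
            mafs[int(entry[0])] = float(entry[2])
    sampler = _CohortSampler(config, rng, mafs)

    n_case_pro = (
        config.n_case_probands
        if config.n_case_probands is not None
        else config.n_trios // 2
    )
    if not 0 <= n_case_pro <= config.n_trios:
        raise ValueError("n_case_probands out of range")

    y_pro, sp_trio, gf_c, gm_c, gc_c = sampler.sample_trios(
        n_case_pro, config.n_trios - n_case_pro
    )
    y_single, sp_single, gs_c = sampler.sample_singletons(config.n_cases, config.n_controls)

    n_trios = config.n_trios
    n_single = config.n_cases + config.n_controls

    # fathers/mothers share the proband's subpopulation
    father_sp = mother_sp = sp_trio
    calls_f = sampler.fill_noncausal(father_sp)
    calls_m = sampler.fill_noncausal(mother_sp)
    calls_c = sampler.transmit(calls_f, calls_m)
    calls_s = sampler.fill_noncausal(sp_single)

    for k, idx in enumerate(sampler.causal_idx):
        calls_f[idx] = gf_c[:, k]
        calls_m[idx] = gm_c[:, k]
        calls_c[idx] = gc_c[:, k]
        calls_s[idx] = gs_c[:, k]

    # interleave trio members family-by-family, then singletons
    calls = np.empty((config.n_snps, 3 * n_trios + n_single), dtype=np.int8)
    calls[:, 0 : 3 * n_trios : 3] = calls_f
    calls[:, 1 : 3 * n_trios : 3] = calls_m
    calls[:, 2 : 3 * n_trios : 3] = calls_c
    calls[:, 3 * n_trios :] = calls_s

    if config.genotyping_error_rate > 0:
        flip = rng.random(calls.shape) < config.genotyping_error_rate
        noise = rng.integers(0, 3, size=calls.shape, dtype=np.int8)
        calls = np.where(flip, noise, calls).astype(np.int8)

    fam, iid, fid, mid, sex, pheno, subpop = [], [], [], [], [], [], []
    for t in range(n_trios):
        f = f"T{t + 1:05d}"
        fam += [f, f, f]
        iid += [f"{f}_F", f"{f}_M", f"{f}_C"]
        fid += ["0", "0", f"{f}_F"]
        mid += ["0", "0", f"{f}_M"]
        sex += [1, 2, int(rng.integers(1, 3))]
        pheno += [-9, -9, int(y_pro[t])]
        subpop += [int(sp_trio[t])] * 3
    for s in range(n_single):
        f = f"S{s + 1:05d}"
        fam.append(f)
        iid.append(f"{f}_1")
        fid.append("0")
        mid.append("0")
        sex.append(int(rng.integers(1, 3)))
        pheno.append(int(y_single[s]))
        subpop.append(int(sp_single[s]))

    pedigree = PedigreeTable(
        family_id=np.array(fam, dtype=object),
        individual_id=np.array(iid, dtype=object),
        father_id=np.array(fid, dtype=object),
        mother_id=np.array(mid, dtype=object),
        sex=np.array(sex, dtype=np.int64),
        stratum=np.full(len(iid), "C1", dtype=object),
        phenotype=np.array(pheno, dtype=np.int8),
    )
    genotypes = GenotypeMatrix(
        snp_ids=np.array([f"snp{i + 1:06d}" for i in range(config.n_snps)], dtype=object),
        chrom=np.full(config.n_snps, "1", dtype=object),
        pos=np.arange(1, config.n_snps + 1, dtype=np.int64) * 1000,
        subject_ids=np.array(iid, dtype=object),
        calls=calls,
    )
    return SimulatedStudy(
        pedigree=pedigree,
        genotypes=genotypes,
        causal_or={int(e[0]): float(e[1]) for e in config.causal_snps},
        subpop=np.array(subpop, dtype=np.int8),
        mafs=mafs,
        config=config,
    )


def write_fixture(study: SimulatedStudy, out_prefix: str) -> dict[str, str]:
    """Write PED/MAP, a covariate TSV and a truth TSV; deterministic given seed."""
    paths = {
        "ped": f"{out_prefix}.ped",
        "map": f"{out_prefix}.map",
        "cov": f"{out_prefix}.cov.tsv",
        "truth": f"{out_prefix}.truth.tsv",
    }
    write_ped(study.pedigree, study.genotypes, paths["ped"], paths["map"])
    cov = pd.DataFrame(
        {
            "subject_id": study.pedigree.individual_id,
            "phenotype": study.pedigree.phenotype.astype(object),
            "stratum": study.pedigree.stratum,
        }
    )
    cov.loc[cov["phenotype"] == -9, "phenotype"] = ""
    cov.to_csv(paths["cov"], sep="\t", index=False)
    study.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths
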