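"""End-to-end orchestration: QC, the single-step analyses, screening,
rank aggregation and the top-K decision, with full reproducibility.

Layout of the output directory::

    qc_population.tsv / qc_family.tsv   per-SNP QC reports
    singletons_only.tsv / pooled.tsv    stratified trend scans
    fbat.tsv                            trio transmission scan
    fisher_all.tsv / weighted_z.tsv     naive all-SNP combinations
    two_step.tsv                        screening ranks + top-K decision
    manifest.json                       config, seed, versions
    run.log                             stage log
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .combination import two_step_decision, weighted_z_pairwise
from .core_data import PedigreeTable, build_trios, filter_snps, read_ped
from .family_tests import fbat_scan
from .population_tests import trend_scan
from .screening import c2bat_scan, conditional_power_screen

logger = logging.getLogger(__name__)

SUGGESTIVE_P = 1e-5


@dataclass
class RunConfig:
    ped: str
    map: str
    out: str
    pheno: str | None = None
    offset: float = 0.3
    top_k: int = 10
    alpha: float = 0.05
    c2bat_fractions: tuple[float, float, float] = (0.75, 0.50, 0.25)
    max_mendel_trios: int = 2
    min_call_rate: float = 0.95
    min_maf: float = 0.01
    seed: int = 0
    extra: dict = field(default_factory=dict)


def _product_strata(pedigree: PedigreeTable) -> np.ndarray:
    """Center x sex cells: one CMH pass adjusts for both."""
    return np.array(
        [f"{s}|{x}" for s, x in zip(pedigree.stratum, pedigree.sex)], dtype=object
    )


def _write_tsv(path: Path, df: pd.DataFrame, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def _bonferroni_header(alpha: float, n_snps: int) -> list[str]:
    thr = alpha / n_snps if n_snps else float("nan")
    return [
        f"n_snps={n_snps}",
        f"bonferroni_threshold={thr:.2g}",
        f"suggestive_threshold={SUGGESTIVE_P:.2g}",
    ]


def run_all(config: RunConfig) -> Path:
    """Execute every analysis stage; identical config+seed gives identical files."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("famcc")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_all_inner(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_all_inner(config: RunConfig, out: Path) -> Path:
    stage = "read_inputs"
    try:
        pedigree, genotypes = read_ped(config.ped, config.map, pheno_path=config.pheno)
        logger.info("loaded %d subjects x %d SNPs", pedigree.n_subjects, genotypes.n_snps)

        stage = "build_trios"
        trios = build_trios(pedigree)
        has_trios = trios.n_trios > 0
        logger.info("%d trios, %d singletons", trios.n_trios, len(trios.singleton_idx))

        stage = "qc"
        pop_subjects = np.concatenate([trios.singleton_idx, trios.offspring_idx])
        geno_pop, qc_pop = filter_snps(
            genotypes,
            trios=None,
            min_call_rate=config.min_call_rate,
            min_maf=config.min_maf,
            subjects=pop_subjects if pop_subjects.size else None,
        )
        qc_pop.write_tsv(out / "qc_population.tsv")
        if has_trios:
            fam_subjects = np.concatenate(
                [trios.father_idx, trios.mother_idx, trios.offspring_idx]
            )
            geno_fam, qc_fam = filter_snps(
                genotypes,
                trios=trios,
                max_mendel_trios=config.max_mendel_trios,
                min_call_rate=config.min_call_rate,
                min_maf=config.min_maf,
                subjects=fam_subjects,
            )
            qc_fam.write_tsv(out / "qc_family.tsv")

        strata = _product_strata(pedigree)

        stage = "singletons_only"
        idx_single = trios.singleton_idx
        if idx_single.size == 0:
            raise RuntimeError("no singleton subjects")
        z_s, p_s = trend_scan(
            geno_pop.calls[:, idx_single],
            pedigree.phenotype[idx_single],
            strata=strata[idx_single],
        )
        _write_tsv(
            out / "singletons_only.tsv",
            pd.DataFrame(
                {
                    "snp_id": geno_pop.snp_ids,
                    "chr": geno_pop.chrom,
                    "bp": geno_pop.pos,
                    "z_trend_singletons": z_s,
                    "p_trend_singletons": p_s,
                }
            ),
            _bonferroni_header(config.alpha, geno_pop.n_snps),
        )

        stage = "pooled"
        idx_pool = np.concatenate([trios.singleton_idx, trios.offspring_idx])
        z_pool, p_pool = trend_scan(
            geno_pop.calls[:, idx_pool],
            pedigree.phenotype[idx_pool],
            strata=strata[idx_pool],
        )
        _write_tsv(
            out / "pooled.tsv",
            pd.DataFrame(
                {
                    "snp_id": geno_pop.snp_ids,
                    "chr": geno_pop.chrom,
                    "bp": geno_pop.pos,
                    "z_trend_pooled": z_pool,
                    "p_trend_pooled": p_pool,
                }
            ),
            _bonferroni_header(config.alpha, geno_pop.n_snps),
        )

        if not has_trios:
            logger.warning("zero trios: family-dependent outputs skipped")
            (out / "NOTICE_no_trios.txt").write_text(
                "No complete trios in input; fbat/fisher/weighted_z/two_step skipped.\n"
            )
            _write_manifest(config, out)
            return out

        stage = "fbat"
        fb = fbat_scan(trios, geno_fam, offset=config.offset)
        _write_tsv(
            out / "fbat.tsv",
            pd.DataFrame(
                {
                    "snp_id": geno_fam.snp_ids,
                    "chr": geno_fam.chrom,
                    "bp": geno_fam.pos,
                    "z_fbat": fb["Z"],
                    "p_fbat": fb["p"],
                    "n_informative": fb["n_informative"],
                }
            ),
            _bonferroni_header(config.alpha, geno_fam.n_snps),
        )

        # SNP universe for combination: intersection of the two QC survivors
        stage = "intersect"
        common, i_pop, i_fam = np.intersect1d(
            geno_pop.snp_ids.astype(str), geno_fam.snp_ids.astype(str), return_indices=True
        )
        order = np.argsort(i_pop)  # keep MAP order
        i_pop, i_fam = i_pop[order], i_fam[order]
        n_common = len(i_pop)
        logger.info("intersection universe: %d SNPs", n_common)

        stage = "fisher_all"
        from .combination import fisher_combine_pairwise

        p_fisher_all = fisher_combine_pairwise(fb["p"][i_fam], p_s[i_pop])
        _write_tsv(
            out / "fisher_all.tsv",
            pd.DataFrame(
                {
                    "snp_id": geno_pop.snp_ids[i_pop],
                    "chr": geno_pop.chrom[i_pop],
                    "bp": geno_pop.pos[i_pop],
                    "p_fbat": fb["p"][i_fam],
                    "p_trend_singletons": p_s[i_pop],
                    "p_fisher": p_fisher_all,
                }
            ),
            _bonferroni_header(config.alpha, n_common),
        )

        stage = "weighted_z"
        p_wz = weighted_z_pairwise(
            fb["p"][i_fam],
            fb["Z"][i_fam],
            trios.n_trios,
            p_s[i_pop],
            z_s[i_pop],
            len(idx_single),
        )
        _write_tsv(
            out / "weighted_z.tsv",
            pd.DataFrame(
                {
                    "snp_id": geno_pop.snp_ids[i_pop],
                    "chr": geno_pop.chrom[i_pop],
                    "bp": geno_pop.pos[i_pop],
                    "p_weighted_z": p_wz,
                }
            ),
            _bonferroni_header(config.alpha, n_common),
        )

        stage = "screening"
        rng = np.random.default_rng(config.seed)
        geno_fam_common = geno_fam.take_snps(i_fam)
        fam_screen = conditional_power_screen(
            trios, geno_fam_common, offset=config.offset, alpha=config.alpha
        )
        cc_screen = c2bat_scan(
            geno_pop.calls[np.ix_(i_pop, idx_single)],
            pedigree.phenotype[idx_single],
            fractions=config.c2bat_fractions,
            rng=rng,
            pos=geno_pop.pos[i_pop],
            snp_ids=geno_pop.snp_ids[i_pop],
        )

        stage = "two_step"
        decision = two_step_decision(
            snp_ids=geno_pop.snp_ids[i_pop],
            rank_family=fam_screen.rank,
            rank_cc=cc_screen.rank,
            p_family=fb["p"][i_fam],
            p_cc=cc_screen.extras["p_test"],
            K=min(config.top_k, n_common),
            alpha=config.alpha,
        )
        decision.insert(1, "chr", geno_pop.chrom[i_pop])
        decision.insert(2, "bp", geno_pop.pos[i_pop])
        decision["screen_power_family"] = fam_screen.score
        decision["screen_score_cc"] = cc_screen.score
        decision = decision.rename(
            columns={"p_family": "p_fbat", "p_cc": "p_c2bat_test"}
        )
        _write_tsv(
            out / "two_step.tsv",
            decision,
            [
                f"n_snps={n_common}",
                f"top_k={min(config.top_k, n_common)}",
                f"per_test_threshold={config.alpha / min(config.top_k, n_common):.2g}",
                f"suggestive_threshold={SUGGESTIVE_P:.2g}",
            ],
        )

        _write_manifest(config, out)
        logger.info("run complete")
        return out
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _write_manifest(config: RunConfig, out: Path) -> None:
    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "versions": {
            "famcc": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
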