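import numpy as np
import pytest

from famcc.core_data import (
    build_trios,
    filter_snps,
    mendel_error_counts,
    mendel_error_trios,
    read_ped,
    write_ped,
)

from .conftest import make_genotypes, make_pedigree, make_trios


def _write(tmp_path, ped_lines, map_lines):
    ped = tmp_path / "x.ped"
    mp = tmp_path / "x.map"
    ped.write_text("\n".join(ped_lines) + "\n")
    mp.write_text("\n".join(map_lines) + "\n")
    return ped, mp


class TestReadPed:
    def test_single_subject_monomorphic_orientation(self, tmp_path):
        # only allele A observed: the counted (minor) allele is the absent one
        ped, mp = _write(tmp_path, ["F1 I1 0 0 1 2 A A"], ["1 rs1 0 100"])
        pedigree, geno = read_ped(ped, mp)
        assert geno.calls[0, 0] == 0
        assert pedigree.phenotype[0] == 1  # PED code 2 -> affected

    def test_half_missing_pair_is_missing_call(self, tmp_path):
        ped, mp = _write(tmp_path, ["F1 I1 0 0 1 2 0 A", "F2 I2 0 0 2 1 A A"], ["1 rs1 0 100"])
        _, geno = read_ped(ped, mp)
        assert geno.calls[0, 0] == -1
        assert geno.calls[0, 1] == 0

    def test_column_count_mismatch_raises(self, tmp_path):
        ped, mp = _write(
            tmp_path,
            ["F1 I1 0 0 1 2 A A C C G G T T A A"],  # 5 SNPs
            ["1 rs1 0 1", "1 rs2 0 2", "1 rs3 0 3", "1 rs4 0 4"],  # MAP: 4
        )
        with pytest.raises(ValueError, match="MAP implies"):
            read_ped(ped, mp)

    def test_duplicate_subject_raises(self, tmp_path):
        ped, mp = _write(
            tmp_path, ["F1 I1 0 0 1 2 A A", "F1 I1 0 0 1 1 A A"], ["1 rs1 0 100"]
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_ped(ped, mp)

    def test_minor_orientation(self, tmp_path):
        # allele G has frequency 5/6 so T must be the counted allele
        ped, mp = _write(
            tmp_path,
            ["F1 I1 0 0 1 2 G G", "F2 I2 0 0 1 1 G G", "F3 I3 0 0 2 1 G T"],
            ["1 rs1 0 100"],
        )
        _, geno = read_ped(ped, mp)
        assert list(geno.calls[0]) == [0, 0, 1]
        assert geno.maf()[0] <= 0.5


def test_roundtrip_write_read(tmp_path, small_study):
    # read_ped output is always minor-oriented, so the round-trip invariant
    # is stated on the oriented matrix
    oriented = small_study.genotypes.orient_minor()
    ped = tmp_path / "rt.ped"
    mp = tmp_path / "rt.map"
    write_ped(small_study.pedigree, oriented, ped, mp)
    ped2, geno2 = read_ped(ped, mp)
    assert np.array_equal(oriented.calls, geno2.calls)
    assert np.array_equal(small_study.pedigree.individual_id, ped2.individual_id)
    assert np.array_equal(small_study.pedigree.phenotype, ped2.phenotype)

    # writing the re-read matrix again reproduces it exactly
    ped3 = tmp_path / "rt2.ped"
    mp3 = tmp_path / "rt2.map"
    write_ped(ped2, geno2, ped3, mp3)
    ped4, geno4 = read_ped(ped3, mp3)
    assert geno2.equals(geno4)
    assert ped2.equals(ped4)


def test_orientation_idempotent(small_study):
    once = small_study.genotypes.orient_minor()
    twice = once.orient_minor()
    assert np.array_equal(once.calls, twice.calls)
    assert np.all((once.maf() <= 0.5) | np.isnan(once.maf()))


class TestBuildTrios:
    def test_family_of_three(self):
        ped = make_pedigree(
            [
                ("F1", "dad", "0", "0", 1, "0", -9),
                ("F1", "mom", "0", "0", 2, "0", -9),
                ("F1", "kid", "dad", "mom", 1, "0", 1),
            ]
        )
        trios = build_trios(ped)
        assert trios.n_trios == 1
        assert trios.offspring_phenotype[0] == 1
        assert len(trios.singleton_idx) == 0

    def test_missing_father_excludes_child_entirely(self):
        ped = make_pedigree(
            [
                ("F1", "mom", "0", "0", 2, "0", -9),
                ("F1", "kid", "0", "mom", 1, "0", 1),
                ("F2", "solo", "0", "0", 1, "0", 0),
            ]
        )
        trios = build_trios(ped)
        assert trios.n_trios == 0
        # the duo child is neither trio member nor singleton
        assert list(trios.singleton_idx) == [2]

    def test_siblings_keep_lowest_individual_id(self):
        ped = make_pedigree(
            [
                ("F1", "dad", "0", "0", 1, "0", -9),
                ("F1", "mom", "0", "0", 2, "0", -9),
                ("F1", "kidB", "dad", "mom", 1, "0", 1),
                ("F1", "kidA", "dad", "mom", 2, "0", 0),
            ]
        )
        trios = build_trios(ped)
        assert trios.n_trios == 1
        assert ped.individual_id[trios.offspring_idx[0]] == "kidA"

    def test_absent_parent_reference_excludes_family(self, caplog):
        ped = make_pedigree(
            [
                ("F1", "mom", "0", "0", 2, "0", -9),
                ("F1", "kid", "ghost", "mom", 1, "0", 1),
            ]
        )
        trios = build_trios(ped)
        assert trios.n_trios == 0


class TestMendel:
    @pytest.mark.parametrize(
        "f,m,x,err",
        [
            (0, 0, 1, True),
            (0, 0, 0, False),
            (2, 0, 1, False),
            (2, 0, 0, True),
            (2, 0, 2, True),
            (1, 1, 0, False),
            (1, 1, 1, False),
            (1, 1, 2, False),
            (2, 2, 2, False),
            (2, 2, 1, True),
        ],
    )
    def test_single_trio_cases(self, f, m, x, err):
        geno = make_genotypes([[f, m, x]])
        trios = make_trios(1, [1])
        assert mendel_error_trios(0, trios, geno) == (1 if err else 0)

    def test_missing_member_skips_trio(self):
        geno = make_genotypes([[0, 0, -1]])
        trios = make_trios(1, [1])
        assert mendel_error_trios(0, trios, geno) == 0

    def test_simulated_data_has_no_errors(self, small_study, small_trios):
        counts = mendel_error_counts(small_trios, small_study.genotypes)
        assert counts.sum() == 0


class TestFilterSnps:
    def _three_trio_setup(self, n_bad_trios):
        # 4 trios; SNP 0 violates transmission in the first n_bad_trios
        calls = np.tile([1, 1, 1], 4)
        geno_row = calls.copy()
        for t in range(n_bad_trios):
            geno_row[3 * t : 3 * t + 2] = [0, 0]  # parents 0/0, child stays 1
        clean = np.tile([0, 1, 0], 4)  # polymorphic, no errors
        geno = make_genotypes(np.vstack([geno_row, clean]))
        trios = make_trios(4, [1, 0, 1, 0])
        return geno, trios

    def test_three_mendel_trios_removed(self):
        geno, trios = self._three_trio_setup(3)
        kept, report = filter_snps(geno, trios, min_call_rate=0.0, min_maf=0.0)
        assert report.reason[0] == "mendel"
        assert report.removed[0]
        assert list(kept.snp_ids) == ["s1"]

    def test_two_mendel_trios_retained(self):
        geno, trios = self._three_trio_setup(2)
        kept, report = filter_snps(geno, trios, min_call_rate=0.0, min_maf=0.0)
        assert not report.removed[0]
        assert "s0" in list(kept.snp_ids)

    def test_mendel_trio_zeroed_at_retained_snp(self):
        geno, trios = self._three_trio_setup(1)
        kept, _ = filter_snps(geno, trios, min_call_rate=0.0, min_maf=0.0)
        # offending trio (first three subjects) set missing at that SNP only
        assert list(kept.calls[0, :3]) == [-1, -1, -1]
        assert np.all(kept.calls[0, 3:] >= 0)
        assert np.all(kept.calls[1] >= 0)

    def test_monomorphic_removed(self):
        geno = make_genotypes([[0, 0, 0, 0], [0, 1, 1, 2]])
        kept, report = filter_snps(geno, None, min_call_rate=0.0, min_maf=0.0)
        assert report.reason[0] == "monomorphic"
        assert list(kept.snp_ids) == ["s1"]

    def test_call_rate_filter(self):
        geno = make_genotypes([[-1, -1, -1, 1], [0, 1, 1, 2]])
        kept, report = filter_snps(geno, None, min_call_rate=0.5, min_maf=0.0)
        assert report.reason[0] == "call_rate"

    def test_all_removed_raises(self):
        geno = make_genotypes([[0, 0, 0, 0]])
        with pytest.raises(RuntimeError, match="no SNPs pass QC"):
            filter_snps(geno, None, min_call_rate=0.0, min_maf=0.0)

    def test_report_tsv(self, tmp_path):
        geno = make_genotypes([[0, 1, 1, 2]])
        _, report = filter_snps(geno, None, min_call_rate=0.0, min_maf=0.0)
        out = tmp_path / "qc.tsv"
        report.write_tsv(out)
        header = out.read_text().splitlines()[0].split("\t")
        assert header == [
            "snp_id", "chr", "bp", "maf", "call_rate", "mendel_trios", "removed", "reason",
        ]
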