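import numpy as np
import pytest
from scipy import stats

from famcc.population_tests import GenotypeCountTable, trend_test
from famcc.screening import (
    ContingencySplit,
    _impute_affected,
    c2bat_scan,
    c2bat_screen,
    c2bat_split,
    c2bat_test,
    conditional_power_scores,
    conditional_power_screen,
)

from .conftest import make_genotypes, make_trios


class TestConditionalPower:
    def test_null_power_equals_alpha(self):
        # constant phenotype: zero slope, delta 0, power exactly alpha
        rng = np.random.default_rng(0)
        f = rng.integers(0, 3, size=(5, 50)).astype(np.int8)
        m = rng.integers(0, 3, size=(5, 50)).astype(np.int8)
        y = np.ones(50, dtype=np.int8)
        power, b, delta, degen = conditional_power_scores(f, m, y, alpha=0.05)
        np.testing.assert_allclose(power, 0.05, atol=1e-12)
        np.testing.assert_allclose(delta, 0.0, atol=1e-12)

    def test_degenerate_proxy_scores_alpha(self):
        # all parents identical: no proxy variance
        f = np.ones((1, 30), dtype=np.int8)
        m = np.ones((1, 30), dtype=np.int8)
        y = np.tile([0, 1], 15).astype(np.int8)
        power, _, _, degen = conditional_power_scores(f, m, y, alpha=0.05)
        assert degen[0]
        assert power[0] == pytest.approx(0.05)

    def test_power_monotone_in_abs_delta(self):
        alpha = 0.05
        z = stats.norm.ppf(1 - alpha / 2)
        deltas = np.linspace(0, 6, 50)
        power = stats.norm.cdf(deltas - z) + stats.norm.cdf(-deltas - z)
        assert np.all(np.diff(power) > 0)
        assert power[0] == pytest.approx(alpha)
        assert np.all(power < 1)

    def test_alpha_does_not_change_ranks(self, small_study, small_trios):
        r1 = conditional_power_screen(small_trios, small_study.genotypes, alpha=0.05)
        r2 = conditional_power_screen(small_trios, small_study.genotypes, alpha=0.01)
        np.testing.assert_array_equal(r1.rank, r2.rank)

    def test_power_bounds(self, small_study, small_trios):
        scan = conditional_power_screen(small_trios, small_study.genotypes, alpha=0.05)
        assert np.all(scan.score >= 0.05 - 1e-12)
        assert np.all(scan.score < 1.0)

    def test_ranks_are_permutation(self, small_study, small_trios):
        scan = conditional_power_screen(small_trios, small_study.genotypes)
        assert sorted(scan.rank) == list(range(1, small_study.genotypes.n_snps + 1))

    def test_rank_monotone_in_score(self, small_study, small_trios):
        scan = conditional_power_screen(small_trios, small_study.genotypes)
        order = np.argsort(scan.rank)
        assert np.all(np.diff(scan.score[order]) <= 1e-12)

    def test_never_reads_offspring_genotypes(self, small_study, small_trios):
        # permuting offspring genotype columns across trios leaves the
        # screen untouched: a code-level independence guarantee
        rng = np.random.default_rng(3)
        base = conditional_power_screen(small_trios, small_study.genotypes)
        calls = small_study.genotypes.calls.copy()
        perm = rng.permutation(small_trios.n_trios)
        kid_cols = small_trios.offspring_idx
        calls[:, kid_cols] = calls[:, kid_cols[perm]]
        shuffled = type(small_study.genotypes)(
            snp_ids=small_study.genotypes.snp_ids,
            chrom=small_study.genotypes.chrom,
            pos=small_study.genotypes.pos,
            subject_ids=small_study.genotypes.subject_ids,
            calls=calls,
        )
        after = conditional_power_screen(small_trios, shuffled)
        np.testing.assert_array_equal(base.rank, after.rank)
        np.testing.assert_allclose(base.score, after.score)

    def test_causal_snp_ranked_high(self):
        from famcc.core_data import build_trios
        from famcc.simulate import SimulationConfig, simulate_cohort

        ranks = []
        for rep in range(20):
            cfg = SimulationConfig(
                n_snps=1000, n_trios=500, n_cases=0, n_controls=0, seed=700 + rep,
                causal_snps=[(0, 2.0, 0.3)],
            )
            study = simulate_cohort(cfg)
            trios = build_trios(study.pedigree)
            scan = conditional_power_screen(trios, study.genotypes)
            ranks.append(scan.rank[0])
        assert np.median(ranks) <= 10

    def test_zero_trios_raises(self, small_study):
        with pytest.raises(ValueError):
            conditional_power_screen(make_trios(0, []), small_study.genotypes)


class TestC2batSplit:
    def test_default_fractions_column_totals(self):
        rng = np.random.default_rng(1)
        case = np.repeat([0, 1, 2], [50, 50, 50])
        ctrl = np.repeat([0, 1, 2], [50, 50, 50])
        split = c2bat_split(case, ctrl, rng=rng)
        # 100 subjects per class; fractions (minor hom, het, major hom) =
        # (0.75, 0.50, 0.25) -> class totals (25, 50, 75) in class order 0,1,2
        np.testing.assert_array_equal(split.testing_col_totals, [25, 50, 75])

    def test_tables_sum_to_full(self):
        rng = np.random.default_rng(2)
        case = rng.integers(0, 3, size=200)
        ctrl = rng.integers(0, 3, size=180)
        split = c2bat_split(case, ctrl, rng=rng)
        a_full = np.bincount(case, minlength=3)[:3]
        u_full = np.bincount(ctrl, minlength=3)[:3]
        np.testing.assert_array_equal(split.screening_a + split.testing_a, a_full)
        np.testing.assert_array_equal(split.screening_u + split.testing_u, u_full)

    def test_zero_fractions_raise(self):
        with pytest.raises(ValueError, match="empty testing table"):
            c2bat_split(np.array([0, 1]), np.array([1, 2]), fractions=(0, 0, 0))

    def test_unit_fractions_move_everything(self):
        rng = np.random.default_rng(3)
        case = rng.integers(0, 3, size=100)
        ctrl = rng.integers(0, 3, size=100)
        split = c2bat_split(case, ctrl, fractions=(1, 1, 1), rng=rng)
        assert split.screening_a.sum() + split.screening_u.sum() == 0
        np.testing.assert_array_equal(split.testing_a, np.bincount(case, minlength=3)[:3])

    def test_missing_calls_dropped(self):
        split = c2bat_split(
            np.array([0, 1, -1]), np.array([2, -1]), fractions=(1, 1, 1),
            rng=np.random.default_rng(0),
        )
        assert split.testing_a.sum() + split.testing_u.sum() == 3


class TestC2batScreen:
    def test_imputed_margins_always_match(self):
        rng = np.random.default_rng(5)
        m = np.array([25, 50, 75])
        for _ in range(1000):
            a_tot = int(rng.integers(0, m.sum() + 1))
            imp = _impute_affected(rng, m, np.asarray(a_tot))
            assert imp.sum() == a_tot
            assert np.all(imp >= 0)
            assert np.all(imp <= m)

    def test_forced_margins_degenerate_scores_zero(self):
        # every testing subject affected, empty screening table: summed
        # table has a single phenotype class -> V = 0 -> score 0
        split = ContingencySplit(
            screening_a=np.zeros(3, dtype=int),
            screening_u=np.zeros(3, dtype=int),
            testing_a=np.array([10, 10, 10]),
            testing_u=np.zeros(3, dtype=int),
        )
        assert c2bat_screen(split, rng=np.random.default_rng(0)) == 0.0

    def test_expected_mode_deterministic(self):
        split = ContingencySplit(
            screening_a=np.array([5, 8, 2]),
            screening_u=np.array([7, 6, 3]),
            testing_a=np.array([3, 4, 2]),
            testing_u=np.array([4, 5, 1]),
        )
        s1 = c2bat_screen(split, mode="expected")
        s2 = c2bat_screen(split, mode="expected")
        assert s1 == s2

    def test_screen_independent_of_test(self):
        # under the null the screening score and testing p are uncorrelated
        rng = np.random.default_rng(11)
        n = 2000
        calls = rng.integers(0, 3, size=(n, 400)).astype(np.int8)
        y = np.repeat([1, 0], 200).astype(np.int8)
        scan = c2bat_scan(calls, y, rng=rng)
        ok = np.isfinite(scan.extras["p_test"])
        rho = stats.spearmanr(scan.score[ok], scan.extras["p_test"][ok]).statistic
        assert abs(rho) < 3 / np.sqrt(ok.sum())


class TestC2batTest:
    def test_balanced_testing_table_p_one(self):
        split = ContingencySplit(
            screening_a=np.zeros(3, dtype=int),
            screening_u=np.zeros(3, dtype=int),
            testing_a=np.array([10, 20, 10]),
            testing_u=np.array([10, 20, 10]),
        )
        res = c2bat_test(split)
        assert res.p == pytest.approx(1.0)

    def test_unit_fractions_reduce_to_full_sample_trend(self):
        rng = np.random.default_rng(6)
        case = rng.integers(0, 3, size=150)
        ctrl = rng.integers(0, 3, size=150)
        split = c2bat_split(case, ctrl, fractions=(1, 1, 1), rng=rng)
        full = GenotypeCountTable(
            a=np.bincount(case, minlength=3)[:3], u=np.bincount(ctrl, minlength=3)[:3]
        )
        assert c2bat_test(split).Z == pytest.approx(trend_test(full).Z)

    def test_degenerate_testing_table_untestable(self):
        split = ContingencySplit(
            screening_a=np.zeros(3, dtype=int),
            screening_u=np.zeros(3, dtype=int),
            testing_a=np.array([10, 0, 0]),
            testing_u=np.array([10, 0, 0]),
        )
        assert not c2bat_test(split).testable


class TestC2batScan:
    def test_scan_matches_split_distribution(self):
        # unit fractions make the scan deterministic: testing table equals
        # the full table, so p_test must equal the plain trend p
        rng = np.random.default_rng(7)
        calls = rng.integers(0, 3, size=(30, 200)).astype(np.int8)
        y = np.repeat([1, 0], 100).astype(np.int8)
        scan = c2bat_scan(calls, y, fractions=(1, 1, 1), rng=rng)
        for j in range(30):
            ref = trend_test(GenotypeCountTable.from_genotypes(calls[j], y))
            if ref.testable:
                assert scan.extras["p_test"][j] == pytest.approx(ref.p)

    def test_rank_permutation_and_tiebreak(self):
        rng = np.random.default_rng(8)
        calls = rng.integers(0, 3, size=(50, 100)).astype(np.int8)
        y = rng.integers(0, 2, size=100).astype(np.int8)
        scan = c2bat_scan(calls, y, rng=rng)
        assert sorted(scan.rank) == list(range(1, 51))
        order = np.argsort(scan.rank)
        assert np.all(np.diff(scan.score[order]) <= 1e-12)
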