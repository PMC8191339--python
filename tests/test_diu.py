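"""Differential isoform usage: table construction, filtering, the chi-squared
test, Bonferroni correction, effect ranking, and statistical behaviour."""

import numpy as np
import pytest
from scipy import stats

import isokit
from isokit import IsoformRecord, SampleInfo, SampleMap, UsageTable
from isokit.diu import (
    UntestableGeneError,
    bonferroni,
    build_usage_table,
    chi2_contingency_test,
    filter_testable_genes,
    max_usage_sd,
    run_diu,
    run_diu_tables,
)
from isokit.simulate import switch_usage_tables

from conftest import make_transcript
from _oracles import oracle_chi2


def _table(counts, gene="g"):
    counts = np.asarray(counts)
    return UsageTable(
        gene_id=gene,
        isoform_ids=[f"i{k}" for k in range(counts.shape[0])],
        condition_ids=[f"c{k}" for k in range(counts.shape[1])],
        counts=counts,
    )


class TestBuildUsageTable:
    def _records(self):
        m1 = make_transcript("isoA", "chr1", "+", [(0, 10)], "g")
        m2 = make_transcript("isoB", "chr1", "+", [(20, 30)], "g")
        return [
            IsoformRecord(m1, {"LPS_1": 10, "LPS_2": 20, "NoStim_1": 0, "pilot": 99}),
            IsoformRecord(m2, {"LPS_1": 50, "LPS_2": 20, "NoStim_1": 0, "pilot": 1}),
        ]

    def _map(self):
        return SampleMap(
            [
                SampleInfo("LPS_1", "LPS", "1"),
                SampleInfo("LPS_2", "LPS", "2"),
                SampleInfo("NoStim_1", "NoStim", "1"),
                SampleInfo("pilot", "NoStim", "1", include=False),
            ]
        )

    def test_relative_usage_normalizes_to_100(self):
        t = _table([[30], [70]])
        assert np.allclose(t.relative_usage[:, 0], [30.0, 70.0])

    def test_replicates_collapse_and_excluded_samples_never_enter(self):
        t = build_usage_table(self._records(), self._map())
        assert t.condition_ids == ["LPS", "NoStim"]
        # pilot reads (99/1) must not appear anywhere
        assert t.counts.tolist() == [[30, 0], [70, 0]]

    def test_zero_total_condition_is_nan_and_untestable(self):
        t = build_usage_table(self._records(), self._map())
        assert np.isnan(t.relative_usage[:, 1]).all()
        assert t.testable_columns.tolist() == [True, False]

    def test_per_sample_columns_when_not_collapsing(self):
        t = build_usage_table(self._records(), self._map(), collapse_replicates=False)
        assert t.condition_ids == ["LPS_1", "LPS_2", "NoStim_1"]

    def test_empty_gene_errors(self):
        with pytest.raises(ValueError):
            build_usage_table([], self._map())


class TestFilterTestableGenes:
    @pytest.mark.parametrize(
        "totals,kept",
        [
            ((60, 55, 10, 5), True),
            ((60, 45, 49, 5), False),
            ((50, 50), True),  # boundary: "at least 50" is inclusive
            ((50, 49), False),
        ],
    )
    def test_read_count_boundaries(self, totals, kept):
        t = _table([list(totals), [0] * len(totals)])
        assert bool(filter_testable_genes([t])) == kept


class TestChiSquared:
    def test_perfect_homogeneity(self):
        stat, df, p = chi2_contingency_test([[50, 50], [50, 50]])
        assert (stat, df, p) == (0.0, 1, 1.0)

    def test_hand_computed_statistic(self):
        # E = 50 everywhere; stat = 4 * 40^2 / 50 = 128
        stat, df, _p = chi2_contingency_test([[90, 10], [10, 90]])
        assert stat == pytest.approx(128.0)
        assert df == 1

    def test_permutation_invariance(self, rng):
        m = rng.integers(0, 50, (4, 3))
        m[0, 0] += 1  # avoid an all-zero matrix
        base = chi2_contingency_test(m)
        perm = chi2_contingency_test(m[::-1][:, ::-1])
        assert base == pytest.approx(perm)

    def test_matches_textbook_oracle_on_random_tables(self, rng):
        """Implementation vs the independently coded E_ij = r_i c_j / N
        formula on 1000 random tables."""
        for _ in range(1000):
            shape = (int(rng.integers(2, 6)), int(rng.integers(2, 6)))
            m = rng.integers(0, 40, shape)
            m[0, 0] += 1
            try:
                got = chi2_contingency_test(m)
            except UntestableGeneError:
                mm = m[m.sum(axis=1) > 0][:, m.sum(axis=0) > 0]
                assert mm.shape[0] < 2 or mm.shape[1] < 2
                continue
            expected = oracle_chi2(m)
            assert got[0] == pytest.approx(expected[0], abs=1e-9)
            assert got[1] == expected[1]
            assert got[2] == pytest.approx(expected[2], rel=1e-9, abs=1e-300)

    def test_degenerate_tables_untestable(self):
        with pytest.raises(UntestableGeneError):
            chi2_contingency_test([[5, 5]])  # single isoform
        with pytest.raises(UntestableGeneError):
            chi2_contingency_test([[5, 0], [3, 0]])  # one usable condition


class TestBonferroni:
    def test_cap_and_significance(self):
        p_adj, sig = bonferroni([0.001, 1e-6], alpha=0.05)
        m = 2
        assert p_adj.tolist() == [0.002, 2e-6]
        assert sig.tolist() == [True, True]
        p_adj, sig = bonferroni([0.001] * 1872, alpha=0.05)
        assert p_adj[0] == 1.0 and not sig[0]

    def test_raw_p_threshold_at_study_scale(self):
        # with m = 1872 tests the raw-p cutoff is 0.05/1872 ~ 2.671e-5
        m = 1872
        below, above = 2.6e-5, 2.8e-5
        _, sig = bonferroni([below] + [1.0] * (m - 1), alpha=0.05)
        assert sig[0]
        _, sig = bonferroni([above] + [1.0] * (m - 1), alpha=0.05)
        assert not sig[0]

    def test_empty_input(self):
        p_adj, sig = bonferroni([])
        assert p_adj.size == 0 and sig.size == 0


class TestMaxUsageSd:
    def test_hand_computed_population_sd(self):
        # usage row (10,10,10,90): mean 30, sum dev^2 = 4800, /4, sqrt = 34.641
        t = _table([[10, 10, 10, 90], [90, 90, 90, 10]])
        assert max_usage_sd(t) == pytest.approx(34.641, abs=1e-3)

    def test_identical_usage_gives_zero(self):
        t = _table([[20, 20], [80, 80]])
        assert max_usage_sd(t) == 0.0

    def test_two_isoform_rows_are_complementary(self):
        t = _table([[10, 40], [90, 60]])
        usage = t.relative_usage
        assert np.std(usage[0]) == pytest.approx(np.std(usage[1]))

    def test_single_condition_flagged(self):
        with pytest.raises(UntestableGeneError):
            max_usage_sd(_table([[10], [90]]))


class TestRunDiu:
    def test_identical_counts_never_significant(self):
        tables = [_table([[40, 40, 40], [60, 60, 60]], gene=f"g{i}") for i in range(5)]
        results, _ = run_diu_tables(tables)
        assert all(r.p_value == pytest.approx(1.0) for r in results)
        assert not any(r.significant for r in results)

    def test_single_isoform_gene_untestable(self):
        results, untestable = run_diu_tables([_table([[100, 100]], gene="solo")])
        assert results == [] and untestable == ["solo"]

    def test_injected_switch_ranks_first(self, rng):
        """One 80/20 -> 20/80 switch gene among 199 null genes at 500
        reads/condition dominates the ranking."""
        tables, switch_ids = switch_usage_tables(
            rng, n_genes=200, n_conditions=4, n_isoforms=2,
            reads_per_condition=500, n_switch=1,
        )
        results, _ = run_diu_tables(tables, min_reads=50, min_conditions=2)
        assert results[0].gene_id == switch_ids[0]
        assert results[0].significant

    def test_gene_grouping_excludes_unassigned(self):
        m1 = make_transcript("a", "chr1", "+", [(0, 10)])
        m2 = make_transcript("b", "chr1", "+", [(20, 30)])
        sm = SampleMap([SampleInfo("s1", "c1"), SampleInfo("s2", "c2")])
        recs = [
            IsoformRecord(m1, {"s1": 60, "s2": 60}),
            IsoformRecord(m2, {"s1": 60, "s2": 60}),
        ]
        results, _ = run_diu(recs, sm, {"a": "g", "b": None})
        assert results == []  # gene g has one grouped isoform -> untestable


class TestStatisticalBehaviour:
    def test_power_monotone_in_reads_and_effect(self, rng):
        """Detection of a usage switch is non-decreasing in sequencing depth
        and in switch magnitude (3x3 grid, 60 replicates each)."""
        reads_grid = [60, 200, 800]
        effect_grid = [0.55, 0.65, 0.80]
        power = np.zeros((3, 3))
        for i, reads in enumerate(reads_grid):
            for j, eff in enumerate(effect_grid):
                hits = 0
                for _ in range(60):
                    tables, switch_ids = switch_usage_tables(
                        rng, n_genes=20, n_conditions=4, n_isoforms=2,
                        reads_per_condition=reads, n_switch=1,
                        switch_usage=(eff, 1 - eff),
                    )
                    results, _ = run_diu_tables(tables, min_reads=50)
                    if any(r.gene_id == switch_ids[0] and r.significant for r in results):
                        hits += 1
                power[i, j] = hits / 60
        slack = 0.10  # two-ish binomial SEs at n=60
        assert (np.diff(power, axis=0) >= -slack).all()  # depth
        assert (np.diff(power, axis=1) >= -slack).all()  # effect size
        assert power[2, 2] > power[0, 0]

    def test_significant_genes_have_larger_usage_sd(self, rng):
        """Direction check mirroring the max-SD ranking: flagged genes sit
        higher in the usage-SD ordering than unflagged ones."""
        tables, _ = switch_usage_tables(
            rng, n_genes=150, n_conditions=4, n_isoforms=2,
            reads_per_condition=300, n_switch=25, switch_usage=(0.75, 0.25),
        )
        results, _ = run_diu_tables(tables)
        sd_sig = [r.max_usage_sd for r in results if r.significant]
        sd_not = [r.max_usage_sd for r in results if not r.significant]
        assert sd_sig and sd_not
        stat = stats.mannwhitneyu(sd_sig, sd_not, alternative="greater")
        assert stat.pvalue < 1e-3
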