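"""HWE chi-square, status grid, and the two marker-QC diagnostics."""

import numpy as np
import pytest
from scipy import stats

from microsat.genotypes import LocusSummary, locus_summaries
from microsat.hwe import (
    HWEStatus,
    anova_from_summaries,
    deficit_vs_missingness,
    genotype_counts,
    hwe_chi2,
    hwe_grid,
    missingness_anova,
)
from microsat.simulate import PopSimSpec, simulate_genotypes

from conftest import make_table


class TestHweChi2:
    def test_exact_hwe_proportions(self):
        res = hwe_chi2({(1, 1): 25, (1, 2): 50, (2, 2): 25})
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1
        assert res.p == pytest.approx(1.0)
        assert res.status is HWEStatus.NON_SIGNIFICANT

    def test_worked_example_chi2_4(self):
        # p=q=0.5 -> expected 25/50/25; chi2 = 1 + 2 + 1 = 4
        res = hwe_chi2({(1, 1): 30, (1, 2): 40, (2, 2): 30})
        assert res.chi2 == pytest.approx(4.0)
        assert res.df == 1
        assert res.p == pytest.approx(stats.chi2.sf(4.0, 1))
        assert res.p == pytest.approx(0.0455, abs=5e-4)
        assert res.status is HWEStatus.SIGNIFICANT

    def test_monomorphic(self):
        res = hwe_chi2({(1, 1): 40})
        assert res.status is HWEStatus.MONOMORPHIC
        assert res.chi2 is None and res.p is None

    def test_untestable_empty(self):
        res = hwe_chi2({})
        assert res.status is HWEStatus.UNTESTABLE

    def test_df_multiallelic(self):
        counts = {(1, 1): 5, (2, 2): 5, (3, 3): 5, (1, 2): 5, (1, 3): 5, (2, 3): 5}
        res = hwe_chi2(counts)
        assert res.df == 3  # k=3 -> k(k-1)/2

    def test_allele_relabeling_invariance(self):
        a = hwe_chi2({(1, 1): 12, (1, 2): 30, (2, 2): 18})
        b = hwe_chi2({(7, 7): 18, (3, 7): 30, (3, 3): 12})
        assert a.chi2 == pytest.approx(b.chi2)
        assert a.p == pytest.approx(b.p)

    def test_low_expected_count_warning(self):
        res = hwe_chi2({(1, 1): 99, (1, 2): 1, (2, 2): 1})
        assert res.low_expected_warning
        ok = hwe_chi2({(1, 1): 25, (1, 2): 50, (2, 2): 25})
        assert not ok.low_expected_warning

    def test_type_one_error_calibration_quick(self):
        rng = np.random.default_rng(3)
        rej = 0
        n_sim = 400
        for _ in range(n_sim):
            counts = rng.multinomial(100, [0.25, 0.5, 0.25])
            res = hwe_chi2({(1, 1): counts[0], (1, 2): counts[1], (2, 2): counts[2]})
            rej += res.p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rej / n_sim - 0.05) < 3 * se + 0.01


class TestHweGrid:
    def test_statuses_and_alphabetical_columns(self):
        table = make_table(
            {
                "zpop": [[(100, 100)], [(100, 100)], [(100, 100)]],
                "apop": [[(100, 102)], [(100, 100)], [(102, 102)]],
            },
            ["locA"],
        )
        grid = hwe_grid(table)
        assert grid.populations == ["apop", "zpop"]
        assert grid.status("locA", "zpop") is HWEStatus.MONOMORPHIC
        assert grid.status("locA", "apop") in (
            HWEStatus.SIGNIFICANT,
            HWEStatus.NON_SIGNIFICANT,
        )

    def test_all_missing_cell_untestable(self):
        table = make_table(
            {"p1": [[None], [None]], "p2": [[(100, 102)], [(100, 100)]]}, ["locA"]
        )
        grid = hwe_grid(table)
        assert grid.status("locA", "p1") is HWEStatus.UNTESTABLE

    def test_adding_all_missing_individual_changes_nothing(self):
        base = make_table(
            {"p": [[(100, 102)], [(100, 100)], [(102, 102)], [(100, 102)]]}, ["locA"]
        )
        plus = make_table(
            {"p": [[(100, 102)], [(100, 100)], [(102, 102)], [(100, 102)], [None]]},
            ["locA"],
        )
        ra = hwe_grid(base).results[("locA", "p")]
        rb = hwe_grid(plus).results[("locA", "p")]
        assert (ra.chi2, ra.df, ra.p, ra.status) == (rb.chi2, rb.df, rb.p, rb.status)

    def test_relabeling_does_not_change_cells(self):
        spec = PopSimSpec(n_pops=3, n_per_pop=20, n_loci=3, n_alleles=3,
                          fst_target=0.05, seed=21)
        table, _ = simulate_genotypes(spec)
        grid = hwe_grid(table)
        for ind in table.individuals:
            ind.population = "renamed_" + ind.population
        grid2 = hwe_grid(table)
        for locus in table.loci:
            for pop in grid.populations:
                assert grid.status(locus, pop) is grid2.status(locus, "renamed_" + pop)

    def test_tsv_and_text_renderings(self):
        table = make_table(
            {"p1": [[(100, 100)], [(100, 100)]], "p2": [[(100, 102)], [(100, 100)]]},
            ["locA"],
        )
        grid = hwe_grid(table)
        tsv = grid.to_tsv().splitlines()
        assert tsv[0] == "locus\tp1\tp2"
        assert tsv[1].startswith("locA\tmonomorphic\t")
        text = grid.to_text_grid()
        assert "." in text  # monomorphic code

    def test_grid_type_one_calibration(self):
        # panmictic simulated data: ~alpha of testable cells significant
        spec = PopSimSpec(n_pops=6, n_per_pop=50, n_loci=40, n_alleles=4,
                          fst_target=0.001, seed=8)
        table, _ = simulate_genotypes(spec)
        grid = hwe_grid(table, alpha=0.05)
        results = list(grid.results.values())
        testable = [r for r in results if r.p is not None]
        assert len(testable) >= 200
        rate = np.mean([r.status is HWEStatus.SIGNIFICANT for r in testable])
        se = np.sqrt(0.05 * 0.95 / len(testable))
        assert abs(rate - 0.05) < 3 * se + 0.01


def _summaries(xs, ys):
    return [
        LocusSummary(f"l{i}", 2, 0.5 - x, 0.5, y)
        for i, (x, y) in enumerate(zip(xs, ys))
    ]


class TestDeficitVsMissingness:
    def test_perfect_monotone_increasing(self):
        res = deficit_vs_missingness(_summaries([0.1, 0.2, 0.3, 0.4], [1, 2, 3, 4]))
        assert res.r_s == pytest.approx(1.0)

    def test_perfect_monotone_decreasing(self):
        res = deficit_vs_missingness(_summaries([0.1, 0.2, 0.3, 0.4], [4, 3, 2, 1]))
        assert res.r_s == pytest.approx(-1.0)

    def test_agrees_with_scipy_spearman(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            x = rng.random(n).round(2)  # rounding forces ties
            y = rng.random(n).round(2)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = deficit_vs_missingness(_summaries(x, y))
            ref_r, ref_p = stats.spearmanr(x, y)
            assert res.r_s == pytest.approx(ref_r, abs=1e-10)
            if abs(ref_r) < 1:
                assert res.p == pytest.approx(ref_p, abs=1e-10)

    def test_exact_permutation_p(self):
        s = _summaries([0.1, 0.3, 0.2, 0.4, 0.35], [1.0, 2.5, 2.0, 4.0, 3.0])
        approx = deficit_vs_missingness(s)
        exact = deficit_vs_missingness(s, exact=True)
        assert exact.r_s == pytest.approx(approx.r_s)
        assert 0 <= exact.p <= 1

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            deficit_vs_missingness(_summaries([0.1, 0.1, 0.1], [1, 2, 3]))

    def test_too_few_loci(self):
        with pytest.raises(ValueError, match=">= 3"):
            deficit_vs_missingness(_summaries([0.1, 0.2], [1, 2]))

    def test_loci_without_data_excluded(self):
        s = _summaries([0.1, 0.2, 0.3, 0.4], [1, 2, 3, 4])
        s.append(LocusSummary("empty", None, None, None, 100.0))
        assert deficit_vs_missingness(s).n == 4

    def test_null_alleles_induce_positive_correlation(self):
        # loci with heavier null-allele load show both more missing data and
        # a larger heterozygote deficit, which this diagnostic should flag
        positives = 0
        n_datasets = 20
        for i in range(n_datasets):
            null = list(np.linspace(0.0, 0.35, 8))
            spec = PopSimSpec(n_pops=2, n_per_pop=60, n_loci=8, n_alleles=6,
                              fst_target=0.01, null_rate=null, seed=300 + i)
            table, _ = simulate_genotypes(spec)
            res = deficit_vs_missingness(locus_summaries(table))
            positives += res.r_s > 0
        assert positives >= 17  # one-sided sign test, p < 1e-3 under fair coin


class TestMissingnessAnova:
    def test_hand_example(self):
        res = missingness_anova({"g1": [1, 3], "g2": [5, 7]})
        assert res.F == pytest.approx(8.0)
        assert (res.df_between, res.df_within) == (1, 2)
        assert res.p == pytest.approx(stats.f.sf(8.0, 1, 2))

    def test_all_equal(self):
        res = missingness_anova({"g1": [2.0, 2.0], "g2": [2.0, 2.0]})
        assert res.F == 0.0
        assert res.p == 1.0

    def test_zero_within_variance(self):
        res = missingness_anova({"g1": [1.0, 1.0], "g2": [2.0, 2.0]})
        assert np.isinf(res.F)
        assert res.p == 0.0

    def test_agrees_with_scipy(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 5))
            groups = {
                f"g{i}": rng.random(int(rng.integers(2, 8))) * 10 for i in range(k)
            }
            res = missingness_anova(groups)
            ref_f, ref_p = stats.f_oneway(*groups.values())
            assert res.F == pytest.approx(float(ref_f), abs=1e-10)
            assert res.p == pytest.approx(float(ref_p), abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            missingness_anova({"g1": [1, 2], "g2": []})

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            missingness_anova({"g1": [1, 2]})

    def test_from_summaries_grouping(self, panel_summaries):
        res = anova_from_summaries(panel_summaries)
        assert (res.df_between, res.df_within) == (3, 6)
        assert set(res.group_means) == {"1", "2", "3", "4"}
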