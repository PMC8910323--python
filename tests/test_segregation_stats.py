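"""Cohort summaries, retention accounting, exact tests and rounding."""

from fractions import Fraction

import pandas as pd
import pytest
from scipy import stats

from edit_heritage import study_tables
from edit_heritage.reports import comparison_table, study_summary
from edit_heritage.segregation_stats import (
    cas9_fraction,
    exact_multinomial_p,
    format_percent,
    inheritance_stability,
    line_retention_reports,
    mutation_rate_summary,
    read_cohort,
    segregation_chisq,
    stability_average,
    write_cohort,
    zygosity_spectrum_summary,
)


class TestFormatPercent:
    @pytest.mark.parametrize(
        "value, mode, decimals, expected",
        [
            (Fraction(100 * 56, 248), "truncate", 1, 22.5),
            (Fraction(100 * 51, 248), "truncate", 2, 20.56),
            (Fraction(100 * 51, 67), "truncate", 0, 76.0),
            (Fraction(100 * 5, 11), "round", 1, 45.5),
            (81.875, "truncate", 1, 81.8),
            (81.875, "round", 1, 81.9),
            (Fraction(100 * 9, 17), "truncate", 1, 52.9),
        ],
    )
    def test_conventions(self, value, mode, decimals, expected):
        assert format_percent(value, mode, decimals) == expected

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            format_percent(1.0, "bankers")


class TestMutationRates:
    def test_study_counts(self):
        cohort, n = study_tables.t0_mutation_cohort()
        rates = mutation_rate_summary(cohort, n)
        assert rates.n_examined == 248
        assert rates.n_mutant_by_locus == {"fuct1": 56, "xylt1": 62}
        assert rates.n_mutant_both == 51
        assert rates.n_mutant_any == 67
        assert rates.locus_rate("fuct1") == Fraction(100 * 56, 248)
        assert rates.dual_proportion == Fraction(100 * 51, 67)

    def test_no_mutants(self):
        cohort = pd.DataFrame(
            {"plant_id": ["a"], "locus": ["fuct1"], "zygosity": ["wild_type"]}
        )
        rates = mutation_rate_summary(cohort, 10)
        assert not rates.dual_defined
        assert rates.dual_proportion == 0

    def test_more_mutants_than_examined_rejected(self):
        cohort = pd.DataFrame(
            {
                "plant_id": ["a", "b"],
                "locus": ["fuct1", "fuct1"],
                "zygosity": ["homozygous", "homozygous"],
            }
        )
        with pytest.raises(ValueError):
            mutation_rate_summary(cohort, 1)


class TestZygositySpectrum:
    def test_t0_panel_fractions(self):
        panel = study_tables.t0_genotypes()
        fuct1 = zygosity_spectrum_summary(panel, "fuct1")
        assert fuct1["homozygous"] == Fraction(9, 17)
        assert fuct1["bi_allelic"] == Fraction(5, 17)
        assert fuct1["wild_type"] == Fraction(3, 17)
        xylt1 = zygosity_spectrum_summary(panel, "xylt1")
        assert xylt1["bi_allelic"] == Fraction(16, 17)
        assert xylt1["wild_type"] == Fraction(1, 17)

    def test_fractions_sum_to_one(self):
        panel = study_tables.t0_genotypes()
        assert sum(zygosity_spectrum_summary(panel, "fuct1").values()) == 1

    def test_unknown_locus_rejected(self):
        with pytest.raises(ValueError):
            zygosity_spectrum_summary(study_tables.t0_genotypes(), "nope")


class TestInheritanceStability:
    def test_per_line_retention_matches_fixture(self):
        cohort = study_tables.t1_transmission("fuct1")
        reports = {r.parent_id: r for r in line_retention_reports(cohort, "fuct1")}
        expected = {
            "Ta75": Fraction(100 * 5, 11),
            "Ta139": Fraction(100 * 5, 8),
            "Ta105": Fraction(100 * 8, 10),
            "Ta106": Fraction(100 * 7, 8),
            "Ta146": Fraction(100 * 7, 10),
            "Ta161": Fraction(100 * 9, 10),
        }
        assert {pid: r.retention for pid, r in reports.items()} == expected

    def test_unexpected_bucket_matches_transcribed_flags(self):
        # progeny marked unexpected in the table must be exactly those the
        # Mendelian rule rejects (chimeric progeny carry the flag for de novo
        # alleles but land in their own bucket)
        for locus in study_tables.LOCI:
            cohort = study_tables.t1_transmission(locus)
            progeny = cohort[cohort["generation"] == "T1"]
            for parent_id, grp in progeny.groupby("parent_id"):
                parent_row = cohort[cohort["plant_id"] == parent_id].iloc[0]
                report = inheritance_stability(parent_row, grp)
                n_flagged_nonchimeric = int(
                    (grp["unexpected"] & (grp["zygosity"] != "chimeric")).sum()
                )
                assert report.counts.get("unexpected", 0) == n_flagged_nonchimeric

    def test_homozygous_line_with_de_novo_switch(self):
        cohort = study_tables.t1_transmission("fuct1")
        parent_row = cohort[cohort["plant_id"] == "Ta105"].iloc[0]
        progeny = cohort[cohort["parent_id"] == "Ta105"]
        report = inheritance_stability(parent_row, progeny)
        # 8 progeny kept +1 bp(T)/+1 bp(T); 2 carry novel +1 bp(G) alleles
        assert report.counts["expected_homozygous"] == 8
        assert report.counts["unexpected"] == 2
        assert report.total == 10

    def test_counts_conserve_total(self):
        for locus in study_tables.LOCI:
            for report in line_retention_reports(
                study_tables.t1_transmission(locus), locus
            ):
                assert sum(report.counts.values()) == report.total

    def test_mismatched_progeny_rejected(self):
        cohort = study_tables.t1_transmission("fuct1")
        parent_row = cohort[cohort["plant_id"] == "Ta105"].iloc[0]
        wrong = cohort[cohort["parent_id"] == "Ta106"]
        with pytest.raises(ValueError):
            inheritance_stability(parent_row, wrong)

    def test_stability_average_modes(self):
        values = [Fraction(100 * 8, 10), Fraction(100 * 7, 8),
                  Fraction(100 * 7, 10), Fraction(100 * 9, 10)]
        assert stability_average(values, "truncate", 1) == 81.8
        assert stability_average(values, "round", 1) == 81.9


class TestSegregationTests:
    def test_perfect_ratio_gives_zero_statistic(self):
        stat, df, p = segregation_chisq([25, 50, 25], (1, 2, 1))
        assert stat == 0.0
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_exact_enumeration_matches_independent_sum(self):
        observed = [2, 4, 3]
        p_pkg = exact_multinomial_p(observed, (1, 2, 1))
        # independent enumeration with plain math
        from itertools import product
        from math import comb

        n = sum(observed)
        probs = (0.25, 0.5, 0.25)

        def pmf(ks):
            c = comb(n, ks[0]) * comb(n - ks[0], ks[1])
            return c * probs[0] ** ks[0] * probs[1] ** ks[1] * probs[2] ** ks[2]

        p_obs = pmf(observed)
        total = sum(
            pmf((a, b, n - a - b))
            for a, b in product(range(n + 1), repeat=2)
            if a + b <= n and pmf((a, b, n - a - b)) <= p_obs * (1 + 1e-9)
        )
        assert p_pkg == pytest.approx(total)

    def test_large_n_uses_chisquare(self):
        observed = [240, 520, 240]
        stat, df, p = segregation_chisq(observed, (1, 2, 1))
        expected = stats.chisquare(observed, [250, 500, 250]).pvalue
        assert p == pytest.approx(float(expected))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            segregation_chisq([0, 0, 0])

    def test_binomial_match_for_two_classes(self):
        p_pkg = exact_multinomial_p([3, 9], (1, 3))
        p_scipy = stats.binomtest(3, 12, 0.25).pvalue
        assert p_pkg == pytest.approx(float(p_scipy))


class TestCas9Fraction:
    def test_study_t2_panel(self):
        t2 = study_tables.t2_panel()
        report = cas9_fraction(t2[t2["generation"] == "T2"])
        assert report.n_carriers == 10
        assert report.n_plants == 20
        assert report.carrier_fraction == Fraction(1, 2)
        assert report.p_vs_half == pytest.approx(1.0)
        # 10/20 is far from 3:1
        assert report.p_vs_three_quarters < 0.05

    def test_exact_binomials(self):
        df = pd.DataFrame({"plant_id": [str(i) for i in range(20)],
                           "cas9": [True] * 15 + [False] * 5})
        report = cas9_fraction(df)
        assert report.p_vs_three_quarters == pytest.approx(
            float(stats.binomtest(15, 20, 0.75).pvalue)
        )

    def test_conflicting_flags_rejected(self):
        df = pd.DataFrame({"plant_id": ["a", "a"], "cas9": [True, False]})
        with pytest.raises(ValueError):
            cas9_fraction(df)


class TestCohortIO:
    def test_round_trip_and_order_invariance(self, tmp_path):
        cohort = study_tables.t1_transmission("fuct1")
        path = tmp_path / "cohort.tsv"
        write_cohort(cohort, path, ["hello"])
        again = read_cohort(path)
        pd.testing.assert_frame_equal(cohort.reset_index(drop=True), again)
        shuffled = cohort.sample(frac=1, random_state=0)
        r1 = line_retention_reports(cohort, "fuct1")
        r2 = line_retention_reports(shuffled, "fuct1")
        assert {x.parent_id: x.retention for x in r1} == {
            x.parent_id: x.retention for x in r2
        }

    def test_duplicate_rows_rejected(self, tmp_path):
        cohort = study_tables.t1_transmission("fuct1")
        path = tmp_path / "dup.tsv"
        write_cohort(pd.concat([cohort, cohort.head(1)]), path)
        with pytest.raises(ValueError):
            read_cohort(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("plant_id\tlocus\np1\tfuct1\n")
        with pytest.raises(ValueError):
            read_cohort(path)


def test_study_summary_agrees_with_printed_values():
    rows = comparison_table()
    assert len(rows) == len(study_tables.PRINTED_SUMMARY)
    disagreements = [(name, v, p) for name, v, p, ok in rows if not ok]
    assert disagreements == []


def test_study_summary_key_values():
    summary = study_summary()
    assert summary["fuct1_mutation_rate_pct"] == 22.5
    assert summary["both_loci_mutation_rate_pct"] == 20.56
    assert summary["homozygous_retention_avg_pct"] == 81.8
    assert summary["bi_allelic_retention_avg_pct"] == 77.4
    assert summary["t2_cas9_carrier_pct"] == 50.0
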