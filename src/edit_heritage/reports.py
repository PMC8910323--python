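"""Headline summary statistics recomputed from the packaged study tables.

Each entry reproduces one printed percentage from the study, using the
rounding convention of the printed cell (the tables mix truncation and
half-up rounding; see ``segregation_stats.format_percent``).
"""

from __future__ import annotations

from . import study_tables
from .segregation_stats import (
    cas9_fraction,
    format_percent,
    inheritance_stability,
    line_retention_reports,
    mutation_rate_summary,
    stability_average,
    zygosity_spectrum_summary,
)


def study_summary() -> dict[str, float]:
    """Recompute every headline percentage from the transcribed tables."""
    out: dict[str, float] = {}

    # T0 mutation-rate accounting (248 regenerants)
    cohort, n_examined = study_tables.t0_mutation_cohort()
    rates = mutation_rate_summary(cohort, n_examined)
    out["fuct1_mutation_rate_pct"] = format_percent(
        rates.locus_rate("fuct1"), "truncate", 1
    )
    out["xylt1_mutation_rate_pct"] = format_percent(
        rates.locus_rate("xylt1"), "truncate", 1
    )
    out["both_loci_mutation_rate_pct"] = format_percent(
        rates.both_locus_rate, "truncate", 2
    )
    out["dual_mutation_proportion_pct"] = format_percent(
        rates.dual_proportion, "truncate", 0
    )

    # T0 zygosity spectrum (17-line panel)
    fuct1 = zygosity_spectrum_summary(study_tables.t0_genotypes(), "fuct1")
    out["t0_fuct1_wild_type_pct"] = format_percent(
        100 * fuct1.get("wild_type", 0), "truncate", 1
    )
    out["t0_fuct1_homozygous_pct"] = format_percent(
        100 * fuct1.get("homozygous", 0), "truncate", 1
    )
    out["t0_fuct1_bi_allelic_pct"] = format_percent(
        100 * fuct1.get("bi_allelic", 0), "truncate", 1
    )
    xylt1 = zygosity_spectrum_summary(study_tables.t0_genotypes(), "xylt1")
    out["t0_xylt1_bi_allelic_pct"] = format_percent(
        100 * xylt1.get("bi_allelic", 0), "truncate", 0
    )
    out["t0_xylt1_wild_type_pct"] = format_percent(
        100 * xylt1.get("wild_type", 0), "truncate", 1
    )

    # T0 -> T1 inheritance stability
    fuct1_reports = {
        r.parent_id: r
        for r in line_retention_reports(study_tables.t1_transmission("fuct1"), "fuct1")
    }
    for line in ("Ta105", "Ta106", "Ta146", "Ta161"):
        out[f"{line.lower()}_fuct1_retention_pct"] = format_percent(
            fuct1_reports[line].retention, "round", 1
        )
    out["ta75_fuct1_wt_retention_pct"] = format_percent(
        fuct1_reports["Ta75"].retention, "round", 1
    )
    out["ta75_fuct1_chimeric_pct"] = format_percent(
        fuct1_reports["Ta75"].fraction_of("chimeric"), "round", 1
    )
    out["ta139_fuct1_wt_retention_pct"] = format_percent(
        fuct1_reports["Ta139"].retention, "round", 1
    )
    homozygous_lines = [
        r.retention for r in fuct1_reports.values() if r.parent_zygosity == "homozygous"
    ]
    out["homozygous_retention_avg_pct"] = stability_average(
        homozygous_lines, "truncate", 1
    )
    xylt1_reports = line_retention_reports(
        study_tables.t1_transmission("xylt1"), "xylt1"
    )
    out["bi_allelic_retention_avg_pct"] = stability_average(
        [r.retention for r in xylt1_reports if r.parent_zygosity == "bi_allelic"],
        "round",
        1,
    )

    # T1 -> T2 stability and transgene segregation (Ta161-1 line)
    t2 = study_tables.t2_panel()
    t2_progeny = t2[t2["generation"] == "T2"]
    cas9 = cas9_fraction(t2_progeny)
    out["t2_cas9_carrier_pct"] = format_percent(100 * cas9.carrier_fraction, "round", 1)
    parent = t2[t2["generation"] == "T1"]
    for locus in study_tables.LOCI:
        report = inheritance_stability(
            parent[parent["locus"] == locus].iloc[0],
            t2_progeny[t2_progeny["locus"] == locus],
        )
        out[f"t2_{locus}_retention_pct"] = format_percent(report.retention, "round", 1)
    return out


def comparison_table() -> list[tuple[str, float, float, bool]]:
    """(name, computed, printed, agree) rows for the reproduce-study report."""
    computed = study_summary()
    rows = []
    for name, printed in study_tables.PRINTED_SUMMARY.items():
        value = computed[name]
        rows.append((name, value, printed, abs(value - printed) < 1e-9))
    return rows
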