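"""Packaged genotype tables from a published tobacco editing study.

The tables transcribe the study's printed results for CRISPR-Cas9 editing of
the *NbFucT1* and *NbXylT1* loci in *Nicotiana benthamiana*: T0 mutation
counts over 248 regenerants, the 17-line T0 genotype/zygosity panel, the
T0->T1 transmission tables for both loci, and the Ta161 T1->T2 panel with
per-plant Cas9 presence.  Raw sequencing reads were never deposited, so these
tables are the only real data the statistics can be checked against; the
synthetic-data module stands in for the read level.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .segregation_stats import COHORT_COLUMNS

_DATA = resources.files(__package__) / "data"

LOCI = ("fuct1", "xylt1")


def _load(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as path:
        df = pd.read_csv(
            path, sep="\t", dtype={"plant_id": str, "parent_id": str},
            keep_default_na=False,
        )
    for col in ("cas9", "unexpected"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False})
    return df


def t0_mutation_counts() -> dict[str, int]:
    """Mutation tallies over the examined T0 population.

    Keys: n_examined, n_fuct1_mutant, n_xylt1_mutant, n_both_loci.
    """
    df = _load("t0_mutation_counts.tsv")
    return {col: int(df[col].iloc[0]) for col in df.columns}


def t0_mutation_cohort() -> tuple[pd.DataFrame, int]:
    """Expand the T0 tallies into a per-plant mutant cohort.

    Returns (cohort, n_examined).  The expansion preserves only the
    mutated/not-mutated structure (51 plants mutant at both loci, 5 at fuct1
    only, 11 at xylt1 only); genotype strings are not recorded at this scale,
    so the genotype column is blank.
    """
    counts = t0_mutation_counts()
    n_both = counts["n_both_loci"]
    n_f_only = counts["n_fuct1_mutant"] - n_both
    n_x_only = counts["n_xylt1_mutant"] - n_both
    rows = []

    def add(plant_id: str, loci: tuple[str, ...]) -> None:
        for locus in loci:
            rows.append(
                {
                    "plant_id": plant_id,
                    "generation": "T0",
                    "parent_id": "",
                    "locus": locus,
                    "genotype": "",
                    "zygosity": "mutant",
                    "cas9": True,
                    "unexpected": False,
                }
            )

    i = 0
    for _ in range(n_both):
        i += 1
        add(f"M{i:03d}", LOCI)
    for _ in range(n_f_only):
        i += 1
        add(f"M{i:03d}", ("fuct1",))
    for _ in range(n_x_only):
        i += 1
        add(f"M{i:03d}", ("xylt1",))
    cohort = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    return cohort, counts["n_examined"]


def t0_genotypes() -> pd.DataFrame:
    """The 17-line T0 genotype and zygosity panel (both loci)."""
    return _load("t0_genotypes.tsv")


def t1_transmission(locus: str) -> pd.DataFrame:
    """T0 parents plus their T1 progeny genotypes at one locus."""
    if locus == "fuct1":
        return _load("t1_fuct1.tsv")
    if locus == "xylt1":
        return _load("t1_xylt1.tsv")
    raise ValueError(f"unknown locus: {locus!r}")


def t2_panel() -> pd.DataFrame:
    """Ta161 line: T0, T1 parent and the 20 T2 progeny at both loci."""
    return _load("t2_ta161.tsv")


# Printed values from the study, used only by the reproduce-study report to
# label the side-by-side comparison; every computed number comes from the
# tables above.
PRINTED_SUMMARY: dict[str, float] = {
    "fuct1_mutation_rate_pct": 22.5,
    "xylt1_mutation_rate_pct": 25.0,
    "both_loci_mutation_rate_pct": 20.56,
    "dual_mutation_proportion_pct": 76.0,
    "t0_fuct1_wild_type_pct": 17.6,
    "t0_fuct1_homozygous_pct": 52.9,
    "t0_fuct1_bi_allelic_pct": 29.4,
    "t0_xylt1_bi_allelic_pct": 94.0,
    "t0_xylt1_wild_type_pct": 5.8,
    "ta161_fuct1_retention_pct": 90.0,
    "ta105_fuct1_retention_pct": 80.0,
    "ta106_fuct1_retention_pct": 87.5,
    "ta146_fuct1_retention_pct": 70.0,
    "ta75_fuct1_wt_retention_pct": 45.5,
    "ta75_fuct1_chimeric_pct": 54.5,
    "ta139_fuct1_wt_retention_pct": 62.5,
    "homozygous_retention_avg_pct": 81.8,
    "bi_allelic_retention_avg_pct": 77.4,
    "t2_cas9_carrier_pct": 50.0,
    "t2_fuct1_retention_pct": 100.0,
    "t2_xylt1_retention_pct": 100.0,
}
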