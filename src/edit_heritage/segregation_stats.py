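"""Summary statistics over genotype cohort tables.

A cohort table has one row per plant-locus with columns
``plant_id, generation, parent_id, locus, genotype, zygosity, cas9,
unexpected``.  The same schema serves the transcribed study tables and the
forward simulator's pedigree output.  All summaries are invariant to row
order.

Percentages are reported as exact fractions plus an explicit rounding mode,
because published tables mix conventions: some cells truncate (56/248 printed
as 22.5%) and others round half-up (5/11 printed as 45.5%).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .allele_model import parse_genotype_label

COHORT_COLUMNS = (
    "plant_id",
    "generation",
    "parent_id",
    "locus",
    "genotype",
    "zygosity",
    "cas9",
    "unexpected",
)

EXACT_TEST_MAX_N = 30


def read_cohort(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"plant_id": str, "parent_id": str},
        keep_default_na=False,
    )
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    for col in ("cas9", "unexpected"):
        if df[col].dtype == object:
            df[col] = df[col].map(
                {"True": True, "False": False, True: True, False: False}
            )
    dup = df.duplicated(subset=["plant_id", "locus"])
    if dup.any():
        raise ValueError("duplicate plant_id x locus rows in cohort table")
    return df


def write_cohort(df: pd.DataFrame, path: Path | str, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


# --------------------------------------------------------------------------
# Rounding
# --------------------------------------------------------------------------


def format_percent(value: float | Fraction, mode: str = "round", decimals: int = 1) -> float:
    """Render a percentage with an explicit convention.

    ``round`` is half-up (so 45.4545 -> 45.5); ``truncate`` drops the excess
    digits (so 81.875 -> 81.8 at one decimal).
    """
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    quantum = Decimal(1).scaleb(-decimals)
    if mode == "round":
        return float(dec.quantize(quantum, rounding=ROUND_HALF_UP))
    if mode == "truncate":
        return float(dec.quantize(quantum, rounding=ROUND_DOWN))
    raise ValueError(f"unknown rounding mode: {mode!r}")


def _pct(numerator: int, denominator: int) -> Fraction:
    return Fraction(100 * numerator, denominator)


# --------------------------------------------------------------------------
# Mutation-rate accounting
# --------------------------------------------------------------------------


@dataclass
class MutationRateSummary:
    """Per-locus and joint mutation rates over an examined T0 population."""

    n_examined: int
    n_mutant_by_locus: dict[str, int]
    n_mutant_both: int
    n_mutant_any: int

    def locus_rate(self, locus: str) -> Fraction:
        return _pct(self.n_mutant_by_locus[locus], self.n_examined)

    @property
    def both_locus_rate(self) -> Fraction:
        return _pct(self.n_mutant_both, self.n_examined)

    @property
    def dual_defined(self) -> bool:
        return self.n_mutant_any > 0

    @property
    def dual_proportion(self) -> Fraction:
        """Share of dual mutants within the mutant population (0 if no mutants)."""
        if not self.dual_defined:
            return Fraction(0)
        return _pct(self.n_mutant_both, self.n_mutant_any)


def mutation_rate_summary(
    t0: pd.DataFrame, n_examined: int, loci: Sequence[str] = ("fuct1", "xylt1")
) -> MutationRateSummary:
    """Count mutant plants per locus / at both loci over ``n_examined`` plants.

    A plant is mutant at a locus when its row there carries any zygosity
    other than wild type; plants without a row at a locus count as unmutated.
    """
    if n_examined <= 0:
        raise ValueError("n_examined must be positive")
    mutant = t0[t0["zygosity"] != "wild_type"]
    by_locus = {
        locus: int(mutant.loc[mutant["locus"] == locus, "plant_id"].nunique())
        for locus in loci
    }
    per_plant = mutant[mutant["locus"].isin(loci)].groupby("plant_id")["locus"].nunique()
    n_any = int(len(per_plant))
    n_both = int((per_plant == len(loci)).sum())
    if n_any > n_examined:
        raise ValueError("more mutant plants than plants examined")
    return MutationRateSummary(n_examined, by_locus, n_both, n_any)


# --------------------------------------------------------------------------
# Zygosity spectrum
# --------------------------------------------------------------------------


def zygosity_spectrum_summary(calls: pd.DataFrame, locus: str) -> dict[str, Fraction]:
    """Class proportions among plants called at one locus."""
    at_locus = calls[calls["locus"] == locus]
    if at_locus.empty:
        raise ValueError(f"no calls at locus {locus!r}")
    known = {"wild_type", "homozygous", "heterozygous", "bi_allelic", "chimeric"}
    bad = set(at_locus["zygosity"]) - known
    if bad:
        raise ValueError(f"unknown zygosity classes: {sorted(bad)}")
    n = len(at_locus)
    counts = at_locus["zygosity"].value_counts()
    return {cls: _pct(int(c), n) / 100 for cls, c in counts.items()}


# --------------------------------------------------------------------------
# Inheritance stability
# --------------------------------------------------------------------------


@dataclass
class RetentionReport:
    """Progeny of one line bucketed by agreement with the parental genotype."""

    parent_id: str
    locus: str
    parent_zygosity: str
    counts: dict[str, int]  # expected_<class>, chimeric, unexpected
    total: int

    @property
    def n_expected(self) -> int:
        return sum(v for k, v in self.counts.items() if k.startswith("expected_"))

    @property
    def retention(self) -> Fraction:
        return _pct(self.n_expected, self.total)

    def fraction_of(self, bucket: str) -> Fraction:
        return _pct(self.counts.get(bucket, 0), self.total)


def _canonical_labels(genotype_label: str) -> tuple[str, ...]:
    return tuple(sorted(parse_genotype_label(genotype_label).allele_labels))


def inheritance_stability(
    parent_row: Mapping[str, object], progeny: pd.DataFrame
) -> RetentionReport:
    """Bucket one line's progeny as expected / chimeric / unexpected.

    The expected set follows Mendelian transmission of the parental pair:
    a homozygous m/m parent can only yield m/m; a bi-allelic m1/m2 parent can
    yield m1/m1, m1/m2 or m2/m2; a heterozygous or wild-type parent yields
    pairs drawn from its own alleles.  Chimeric progeny form their own bucket;
    any non-chimeric progeny carrying an allele outside the parental set
    (compared at label level, inserted base included) is unexpected.
    """
    parent_id = str(parent_row["plant_id"])
    locus = str(parent_row["locus"])
    if progeny.empty:
        raise ValueError(f"no progeny rows for {parent_id} at {locus}")
    if not (progeny["parent_id"] == parent_id).all():
        raise ValueError("progeny rows do not all name the given parent")
    if not (progeny["locus"] == locus).all():
        raise ValueError("progeny rows are not all at the parent's locus")

    parent_genotype = parse_genotype_label(str(parent_row["genotype"]))
    parent_labels = set(parent_genotype.allele_labels)
    parent_zygosity = str(parent_row["zygosity"])

    counts: dict[str, int] = {}
    for _, row in progeny.iterrows():
        zygosity = str(row["zygosity"])
        if zygosity == "chimeric":
            bucket = "chimeric"
        else:
            labels = _canonical_labels(str(row["genotype"]))
            if set(labels) <= parent_labels:
                bucket = f"expected_{zygosity}"
            else:
                bucket = "unexpected"
        counts[bucket] = counts.get(bucket, 0) + 1
    return RetentionReport(parent_id, locus, parent_zygosity, counts, len(progeny))


def line_retention_reports(cohort: pd.DataFrame, locus: str) -> list[RetentionReport]:
    """Retention reports for every parent line with progeny at one locus."""
    at_locus = cohort[cohort["locus"] == locus]
    reports = []
    for parent_id, progeny in at_locus.groupby("parent_id"):
        if not parent_id:
            continue
        parent_rows = at_locus[at_locus["plant_id"] == parent_id]
        if parent_rows.empty:
            raise ValueError(f"parent {parent_id!r} has no row at locus {locus!r}")
        reports.append(inheritance_stability(parent_rows.iloc[0], progeny))
    if not reports:
        raise ValueError(f"no parent-progeny structure at locus {locus!r}")
    return reports


def stability_average(
    percentages: Iterable[float | Fraction], mode: str = "round", decimals: int = 1
) -> float:
    """Arithmetic mean of per-line retention percentages, then round/truncate."""
    values = list(percentages)
    if not values:
        raise ValueError("no percentages supplied")
    total = sum(Fraction(v) if not isinstance(v, Fraction) else v for v in values)
    return format_percent(total / len(values), mode=mode, decimals=decimals)


# --------------------------------------------------------------------------
# Segregation tests
# --------------------------------------------------------------------------


def exact_multinomial_p(observed: Sequence[int], ratio: Sequence[float]) -> float:
    """Exact multinomial goodness-of-fit p-value by outcome enumeration.

    The p-value is the total probability of all outcomes no more probable
    than the observed one under the null proportions.
    """
    observed = [int(x) for x in observed]
    n = sum(observed)
    probs = np.asarray(ratio, dtype=float)
    probs = probs / probs.sum()
    dist = stats.multinomial(n, probs)
    p_obs = dist.pmf(observed)
    k = len(observed)

    total = 0.0
    # enumerate compositions of n into k parts
    def compositions(remaining: int, parts: int):
        if parts == 1:
            yield (remaining,)
            return
        for first in range(remaining + 1):
            for rest in compositions(remaining - first, parts - 1):
                yield (first, *rest)

    for outcome in compositions(n, k):
        p = dist.pmf(outcome)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return float(min(total, 1.0))


def segregation_chisq(
    observed: Sequence[int],
    ratio: Sequence[float] = (1, 2, 1),
    exact: Optional[bool] = None,
) -> tuple[float, int, float]:
    """Pearson chi-square GOF against an expected ratio such as 1:2:1.

    Returns ``(statistic, df, p)``.  For small totals (<= 30, typical line
    sizes) the p-value is computed by exact multinomial enumeration unless
    ``exact`` is forced.
    """
    observed = [int(x) for x in observed]
    n = sum(observed)
    if n == 0:
        raise ValueError("total count is zero")
    if len(observed) != len(ratio) or any(r <= 0 for r in ratio):
        raise ValueError("ratio must be positive and match the observed classes")
    probs = np.asarray(ratio, dtype=float)
    probs = probs / probs.sum()
    expected = n * probs
    statistic = float(((np.asarray(observed) - expected) ** 2 / expected).sum())
    df = len(observed) - 1
    if exact is None:
        exact = n <= EXACT_TEST_MAX_N
    if exact:
        p = exact_multinomial_p(observed, ratio)
    else:
        p = float(stats.chisquare(observed, expected).pvalue)
    return statistic, df, p


# --------------------------------------------------------------------------
# Transgene fraction
# --------------------------------------------------------------------------


@dataclass
class Cas9Report:
    n_carriers: int
    n_plants: int
    p_vs_half: float
    p_vs_three_quarters: float

    @property
    def carrier_fraction(self) -> Fraction:
        return Fraction(self.n_carriers, self.n_plants)


def cas9_fraction(progeny: pd.DataFrame) -> Cas9Report:
    """Carrier fraction among progeny plants plus exact binomial tests.

    Tests the carrier count against both transmission nulls: 1:1 (the
    empirically reported segregation) and 3:1 (hemizygous selfing).
    """
    if "cas9" not in progeny.columns or progeny["cas9"].isna().any():
        raise ValueError("progeny rows must carry a cas9 flag")
    per_plant = progeny[["plant_id", "cas9"]].drop_duplicates()
    if per_plant["plant_id"].duplicated().any():
        raise ValueError("conflicting cas9 flags for the same plant")
    n = len(per_plant)
    if n == 0:
        raise ValueError("no progeny rows")
    carriers = int(per_plant["cas9"].sum())
    return Cas9Report(
        n_carriers=carriers,
        n_plants=n,
        p_vs_half=float(stats.binomtest(carriers, n, 0.5).pvalue),
        p_vs_three_quarters=float(stats.binomtest(carriers, n, 0.75).pvalue),
    )
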