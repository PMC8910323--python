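"""Threshold rules mapping an allele spectrum to a zygosity class.

The deep-sequencing convention implemented here: a plant is *homozygous* when
one mutation type exceeds 98% of reads, *wild type* when no mutation type
reaches the chimera floor (5%), *bi-allelic* when exactly two mutation types
each sit in the 40-50% band, *heterozygous* when exactly one does with the
remainder wild type, and *chimeric* otherwise (two or more mutations mixed in
irregular ratios, each typically 5-30%).  A tolerance tau (default 0.10)
widens the 40-50% band to absorb sampling noise; the reference allele counts
as a spectrum member but never as a mutation type.  Every spectrum receives
exactly one class, and each call records which rule fired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from .amplicon_caller import AlleleSpectrum

WT_LABEL = "WT"

CLASS_NAMES = ("wild_type", "homozygous", "heterozygous", "bi_allelic", "chimeric")


@dataclass(frozen=True)
class ClassifierThresholds:
    """Frequency bands of the zygosity rules (fractions of retained reads)."""

    homo_min: float = 0.98
    het_lo: float = 0.40
    het_hi: float = 0.50
    chimera_lo: float = 0.05
    chimera_hi: float = 0.30
    tolerance: float = 0.10

    def __post_init__(self) -> None:
        ok = (
            0 < self.chimera_lo <= self.chimera_hi < self.het_lo
            and self.het_lo <= self.het_hi < self.homo_min <= 1
            and self.tolerance >= 0
            and self.het_hi + self.tolerance < self.homo_min
        )
        if not ok:
            raise ValueError("threshold bands must be ordered and disjoint")

    @property
    def band(self) -> tuple[float, float]:
        return (self.het_lo - self.tolerance, self.het_hi + self.tolerance)


@dataclass
class ZygosityCall:
    class_name: str
    alleles: dict[str, float]  # label -> frequency (mutant alleles only)
    rule: str
    reference_freq: float = 0.0

    def __post_init__(self) -> None:
        n_mut = len(self.alleles)
        expected = {
            "wild_type": n_mut == 0,
            "homozygous": n_mut == 1,
            "heterozygous": n_mut == 1,
            "bi_allelic": n_mut == 2,
            # chimeric is the catch-all; it usually carries >= 2 mutant
            # alleles but a lone out-of-band mutation (e.g. 0.70) lands here
            "chimeric": n_mut >= 1,
        }
        if self.class_name not in expected:
            raise ValueError(f"unknown class {self.class_name!r}")
        if not expected[self.class_name]:
            raise ValueError(
                f"{self.class_name} call cannot carry {n_mut} mutant alleles"
            )


def classify_spectrum(
    spectrum: AlleleSpectrum | Mapping[str, float],
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> ZygosityCall:
    """Classify one normalised allele spectrum.

    Rules fire in fixed precedence: homozygous, wild type, bi-allelic,
    heterozygous, then chimeric as the catch-all.  Mutation types are
    aggregated at the label level, so two reads placing the same indel at
    slightly different offsets count as one type.
    """
    if isinstance(spectrum, AlleleSpectrum):
        by_label = spectrum.by_label()
    else:
        by_label = dict(spectrum)
    if not by_label:
        raise ValueError("empty spectrum")
    total = sum(by_label.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"spectrum not normalised (sums to {total})")

    ref_freq = by_label.get(WT_LABEL, 0.0)
    mutants = {lab: f for lab, f in by_label.items() if lab != WT_LABEL}
    t = thresholds
    lo, hi = t.band

    if any(f > t.homo_min for f in mutants.values()):
        top = max(mutants, key=mutants.get)
        return ZygosityCall(
            "homozygous", {top: mutants[top]}, rule="one_mutation_above_98pct",
            reference_freq=ref_freq,
        )
    if all(f < t.chimera_lo for f in mutants.values()):
        return ZygosityCall(
            "wild_type", {}, rule="no_mutation_at_or_above_floor",
            reference_freq=ref_freq,
        )
    in_band = {lab: f for lab, f in mutants.items() if lo <= f <= hi}
    if len(mutants) == 2 and len(in_band) == 2 and ref_freq <= t.chimera_lo:
        return ZygosityCall(
            "bi_allelic", in_band, rule="two_mutations_in_het_band",
            reference_freq=ref_freq,
        )
    if len(mutants) == 1 and len(in_band) == 1:
        return ZygosityCall(
            "heterozygous", in_band, rule="one_mutation_in_het_band",
            reference_freq=ref_freq,
        )
    return ZygosityCall(
        "chimeric",
        {lab: f for lab, f in mutants.items() if f >= t.chimera_lo},
        rule="catch_all_mixed_ratios",
        reference_freq=ref_freq,
    )


def classify_cohort(
    spectra: Mapping[tuple[str, str], AlleleSpectrum],
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    truth: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, Optional[pd.DataFrame], Optional[dict[str, float]]]:
    """Classify every (plant, locus) spectrum in a cohort.

    Returns the calls table and, when a truth table (columns plant_id, locus,
    zygosity) is supplied, a confusion matrix (rows = truth) plus per-class
    recovery rates.
    """
    if not spectra:
        raise ValueError("no spectra supplied")
    keys = list(spectra)
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate plant-locus keys")

    rows = []
    for (plant_id, locus), spectrum in spectra.items():
        call = classify_spectrum(spectrum, thresholds)
        rows.append(
            {
                "plant_id": plant_id,
                "locus": locus,
                "zygosity": call.class_name,
                "alleles": "/".join(sorted(call.alleles)) or WT_LABEL,
                "frequencies": ";".join(
                    f"{lab}={f:.4f}" for lab, f in sorted(call.alleles.items())
                ),
                "rule": call.rule,
            }
        )
    calls = pd.DataFrame(rows)

    if truth is None or truth.empty:
        return calls, None, None
    merged = calls.merge(
        truth[["plant_id", "locus", "zygosity"]],
        on=["plant_id", "locus"],
        suffixes=("_called", "_true"),
    )
    confusion = pd.crosstab(merged["zygosity_true"], merged["zygosity_called"])
    recovery = {
        cls: float((grp["zygosity_called"] == cls).mean())
        for cls, grp in merged.groupby("zygosity_true")
    }
    return calls, confusion, recovery
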