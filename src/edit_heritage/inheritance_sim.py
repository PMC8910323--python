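"""Forward simulation of selfed progeny at Cas9-edited loci.

Each progeny plant receives two gametes per locus (alleles drawn uniformly
from a diploid parent, or in proportion to germline sector fractions from a
chimeric parent) and inherits the Cas9 transgene per the chosen segregation
mode (3:1 for a hemizygous single-locus insertion under selfing, or the
empirical 1:1 alternative).  When Cas9 is present, each transmitted wild-type
allele may be edited de novo: an early (pre-first-division) edit replaces the
allele with a fresh indel; a late edit converts only a sector of the plant,
producing a chimera.  Edited alleles never mutate again, so fully mutant
parents always breed true -- the mechanism behind the observed stability of
homozygous lines across generations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .allele_model import (
    DELETION,
    INSERTION,
    Allele,
    Genotype,
    zygosity_of,
)
from .synthetic_data import (
    CHIMERA_SECTOR_HI,
    CHIMERA_SECTOR_LO,
    DEFAULT_DELETION_SIZES,
    TruthPlant,
)

MENDELIAN_3_1 = "mendelian_3_1"
OBSERVED_1_1 = "observed_1_1"

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimParams:
    """Transmission-model parameters.

    p_edit: probability a transmitted wild-type allele is edited when Cas9 is
    present.  p_late: given an edit, probability it happens after the first
    zygotic division (chimera) rather than before (clean substitution).  The
    indel spectrum gives the insertion weight and deletion-size weights over
    1-11 bp.
    """

    p_edit: float = 0.5
    p_late: float = 0.5
    insertion_weight: float = 0.5
    deletion_size_weights: tuple[float, ...] = tuple(
        1.0 / len(DEFAULT_DELETION_SIZES) for _ in DEFAULT_DELETION_SIZES
    )
    transgene_mode: str = MENDELIAN_3_1
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_edit, self.p_late, self.insertion_weight):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.deletion_size_weights) - 1.0) > 1e-9:
            raise ValueError("deletion-size weights must sum to 1")
        if self.transgene_mode not in (MENDELIAN_3_1, OBSERVED_1_1):
            raise ValueError(f"invalid transgene mode: {self.transgene_mode!r}")


@dataclass
class ProgenyRecord:
    """One simulated progeny plant plus its transmission provenance."""

    plant: TruthPlant
    inherited: dict[str, tuple[Allele, Allele]]  # gametes as sampled, per locus
    de_novo: dict[str, tuple[bool, bool]]  # whether each gamete allele was edited


def segregate_transgene(
    parent_cas9: bool, mode: str, rng: np.random.Generator
) -> bool:
    """Sample transgene presence in one selfed progeny."""
    if not parent_cas9:
        return False
    if mode == MENDELIAN_3_1:
        return bool(rng.random() < 0.75)
    if mode == OBSERVED_1_1:
        return bool(rng.random() < 0.5)
    raise ValueError(f"invalid transgene mode: {mode!r}")


def sample_gamete(parent: TruthPlant, locus: str, rng: np.random.Generator) -> Allele:
    """Draw one gamete allele: uniform over a diploid pair, or by sector fraction."""
    genotype = parent.genotypes[locus]
    weights = genotype.normalized_fractions()
    idx = rng.choice(len(genotype.alleles), p=np.asarray(weights))
    return genotype.alleles[int(idx)]


def draw_de_novo_allele(params: SimParams, rng: np.random.Generator) -> Allele:
    if rng.random() < params.insertion_weight:
        return Allele(INSERTION, 1, _BASES[int(rng.integers(4))])
    size = int(
        rng.choice(DEFAULT_DELETION_SIZES, p=np.asarray(params.deletion_size_weights))
    )
    return Allele(DELETION, size)


def _progeny_genotype(
    gametes: tuple[Allele, Allele],
    cas9: bool,
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[Genotype, tuple[bool, bool]]:
    """Apply possible de novo editing of transmitted WT alleles to one zygote."""
    # each slot: (allele, weight, de_novo); late edits split a slot in two
    slots: list[tuple[Allele, float, bool]] = [
        (gametes[0], 0.5, False),
        (gametes[1], 0.5, False),
    ]
    de_novo_flags = [False, False]
    if cas9 and params.p_edit > 0:
        out: list[tuple[Allele, float, bool]] = []
        for i, (allele, weight, _flag) in enumerate(slots):
            if allele.is_mutant or rng.random() >= params.p_edit:
                out.append((allele, weight, False))
                continue
            new_allele = draw_de_novo_allele(params, rng)
            de_novo_flags[i] = True
            if rng.random() < params.p_late:
                # late edit: only a sector of the plant carries the new allele
                frac = float(rng.uniform(CHIMERA_SECTOR_LO, CHIMERA_SECTOR_HI))
                frac = min(frac, weight - 1e-6)
                out.append((allele, weight - frac, False))
                out.append((new_allele, frac, True))
            else:
                out.append((new_allele, weight, True))
        slots = out

    if len(slots) == 2:
        genotype = Genotype((slots[0][0], slots[1][0]))
    else:
        alleles = tuple(s[0] for s in slots)
        fractions = tuple(s[1] for s in slots)
        genotype = Genotype(alleles, fractions)
    return genotype, (de_novo_flags[0], de_novo_flags[1])


def self_progeny(
    parent: TruthPlant,
    params: SimParams,
    n: int,
    seed: Optional[int] = None,
) -> list[ProgenyRecord]:
    """Simulate ``n`` selfed progeny of one parent across all its loci."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    progeny: list[ProgenyRecord] = []
    for i in range(n):
        cas9 = segregate_transgene(parent.cas9_present, params.transgene_mode, rng)
        genotypes: dict[str, Genotype] = {}
        inherited: dict[str, tuple[Allele, Allele]] = {}
        de_novo: dict[str, tuple[bool, bool]] = {}
        for locus in parent.genotypes:
            gametes = (
                sample_gamete(parent, locus, rng),
                sample_gamete(parent, locus, rng),
            )
            genotype, flags = _progeny_genotype(gametes, cas9, params, rng)
            genotypes[locus] = genotype
            inherited[locus] = gametes
            de_novo[locus] = flags
        child = TruthPlant(
            plant_id=f"{parent.plant_id}-{i + 1}",
            generation=_next_generation(parent.generation),
            genotypes=genotypes,
            cas9_present=cas9,
            parent_id=parent.plant_id,
        )
        progeny.append(ProgenyRecord(child, inherited, de_novo))
    return progeny


def _next_generation(generation: str) -> str:
    order = ["T0", "T1", "T2", "T3"]
    try:
        return order[order.index(generation) + 1]
    except (ValueError, IndexError):
        return generation + "+1"


def progeny_table(records: Sequence[ProgenyRecord]) -> pd.DataFrame:
    """Pedigree output in the cohort-table schema (one row per plant-locus)."""
    rows = []
    for rec in records:
        plant = rec.plant
        for locus, genotype in plant.genotypes.items():
            rows.append(
                {
                    "plant_id": plant.plant_id,
                    "generation": plant.generation,
                    "parent_id": plant.parent_id or "",
                    "locus": locus,
                    "genotype": genotype.label,
                    "zygosity": zygosity_of(genotype),
                    "cas9": plant.cas9_present,
                    "unexpected": any(rec.de_novo[locus]),
                }
            )
    return pd.DataFrame(rows)
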