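"""Synthetic amplicon-sequencing data: target sites, plants, reads, cohorts.

The generator emulates targeted deep sequencing of a diploid plant at a Cas9
cut site: every read is drawn from one allelic state of the plant (each
chromosome with probability 1/2 for a diploid; chimeric sectors in proportion
to their fractions), the corresponding mutant amplicon is computed, a fixed
window around the cut is extracted, and i.i.d. substitution errors are
applied.  Base qualities are constant (Phred 30); downstream stages never use
them.

Emulated study conditions: guides with 30% and 60% GC protospacers targeting
the first exon on the reverse strand; insertions are single-base additions
with a random base; deletion sizes range over 1-11 bp; chimeric plants carry
two or more mutant alleles with sector fractions between 0.05 and 0.30.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .allele_model import (
    DELETION,
    INSERTION,
    Allele,
    Genotype,
    REFERENCE_ALLELE,
    TargetSite,
    apply_allele,
    reverse_complement,
    zygosity_of,
)

PHRED33_Q30 = "?"  # chr(30 + 33)

DEFAULT_DELETION_SIZES = tuple(range(1, 12))
CHIMERA_SECTOR_LO = 0.05
CHIMERA_SECTOR_HI = 0.30

ZYGOSITY_CLASSES = ("wild_type", "homozygous", "heterozygous", "bi_allelic", "chimeric")


@dataclass
class TruthPlant:
    """Ground-truth plant: genotypes per locus plus transgene state."""

    plant_id: str
    generation: str  # T0 | T1 | T2
    genotypes: dict[str, Genotype]
    cas9_present: bool = True
    parent_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.generation == "T0" and self.parent_id is not None:
            raise ValueError("T0 plants have no parent")


@dataclass(frozen=True)
class ReadSimParams:
    """Read-simulation knobs: depth, substitution error rate, read window."""

    n_reads: int = 2000
    error_rate: float = 0.001
    read_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must lie in [0, 0.05]")
        if self.read_length < 30:
            raise ValueError("read_length too short")


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str

    def to_fastq(self) -> str:
        return f"@{self.read_id}\n{self.sequence}\n+\n{PHRED33_Q30 * len(self.sequence)}\n"


def write_fastq(reads: Iterable[SimulatedRead], path: Path | str) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(read.to_fastq())


def read_fastq(path: Path | str) -> list[SimulatedRead]:
    from Bio import SeqIO

    return [
        SimulatedRead(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")
    ]


# --------------------------------------------------------------------------
# Target generation
# --------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_GC = np.array(list("GC"))
_AT = np.array(list("AT"))


def generate_target(
    gc_fraction: float,
    amplicon_length: int = 300,
    strand: str = "plus",
    seed: int = 0,
    site_id: Optional[str] = None,
) -> TargetSite:
    """Random amplicon embedding a 20-nt protospacer of exact GC content + NGG PAM.

    The protospacer carries exactly ``round(20 * gc_fraction)`` G/C bases, so
    ``gc_fraction`` must be a multiple of 0.05.  The cut site lands near the
    amplicon centre.  Deterministic per seed.
    """
    if amplicon_length < 100:
        raise ValueError("amplicon_length must be >= 100")
    n_gc = gc_fraction * 20
    if abs(n_gc - round(n_gc)) > 1e-9:
        raise ValueError(f"gc_fraction {gc_fraction} not representable on 20 nt")
    n_gc = int(round(n_gc))
    rng = np.random.default_rng(seed)

    proto = np.empty(20, dtype="<U1")
    gc_positions = rng.choice(20, size=n_gc, replace=False)
    mask = np.zeros(20, dtype=bool)
    mask[gc_positions] = True
    proto[mask] = rng.choice(_GC, size=n_gc)
    proto[~mask] = rng.choice(_AT, size=20 - n_gc)
    protospacer = "".join(proto)
    pam = str(rng.choice(_BASES)) + "GG"

    cassette = protospacer + pam  # guide-strand orientation
    if strand == "minus":
        cassette = reverse_complement(cassette)
    # place the cassette so the cut is near the centre of the amplicon
    start = (amplicon_length - len(cassette)) // 2
    amplicon = "".join(rng.choice(_BASES, size=amplicon_length))
    amplicon = amplicon[:start] + cassette + amplicon[start + len(cassette) :]

    if strand == "plus":
        ps, pe, pam_start = start, start + 20, start + 20
    else:
        pam_start, ps, pe = start, start + 3, start + 23
    return TargetSite(
        site_id=site_id or f"site_gc{int(round(gc_fraction * 100))}",
        reference=amplicon,
        protospacer_start=ps,
        protospacer_end=pe,
        pam_start=pam_start,
        strand=strand,
    )


# --------------------------------------------------------------------------
# Read simulation
# --------------------------------------------------------------------------


def _allele_window(site: TargetSite, allele: Allele, read_length: int) -> str:
    """Error-free read template: window of the mutant amplicon centred on the cut."""
    mutated = apply_allele(site, allele)
    if read_length > len(mutated):
        raise ValueError("read_length exceeds the mutant amplicon length")
    start = site.cut_offset - read_length // 2
    start = max(0, min(start, len(mutated) - read_length))
    return mutated[start : start + read_length]


def simulate_reads(
    plant: TruthPlant,
    site: TargetSite,
    params: ReadSimParams,
    locus: Optional[str] = None,
) -> list[SimulatedRead]:
    """Simulate ``n_reads`` amplicon reads for one plant at one target site.

    Reads are drawn per allelic state (diploid: 1/2 each; chimeric: per sector
    fraction), then subjected to i.i.d. substitution errors.  Deterministic
    per ``params.seed``.
    """
    locus = locus or site.site_id
    if locus not in plant.genotypes:
        raise ValueError(f"plant {plant.plant_id} has no genotype at locus {locus!r}")
    genotype = plant.genotypes[locus]

    max_extent = max(
        (abs(a.start_offset) + a.size for a in genotype.alleles), default=0
    )
    if params.read_length < 2 * (max_extent + 10):
        raise ValueError(
            "read_length too short to span the largest event plus flanking window"
        )

    windows = [_allele_window(site, a, params.read_length) for a in genotype.alleles]
    weights = np.asarray(genotype.normalized_fractions())

    rng = np.random.default_rng(params.seed)
    assignment = rng.choice(len(windows), size=params.n_reads, p=weights)
    n_err = rng.binomial(params.read_length, params.error_rate, size=params.n_reads)

    reads: list[SimulatedRead] = []
    for i in range(params.n_reads):
        seq = windows[assignment[i]]
        if n_err[i]:
            pos = rng.choice(params.read_length, size=n_err[i], replace=False)
            chars = list(seq)
            for p in pos:
                choices = [b for b in "ACGT" if b != chars[p]]
                chars[p] = choices[rng.integers(3)]
            seq = "".join(chars)
        reads.append(SimulatedRead(f"{plant.plant_id}:{locus}:{i:06d}", seq))
    return reads


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------


def _random_mutant_allele(
    rng: np.random.Generator,
    insertion_weight: float = 0.5,
    deletion_sizes: Sequence[int] = DEFAULT_DELETION_SIZES,
    exclude: frozenset[str] = frozenset(),
) -> Allele:
    """Draw one indel allele: +1 bp with random base, or a 1-11 bp deletion."""
    for _ in range(100):
        if rng.random() < insertion_weight:
            allele = Allele(INSERTION, 1, str(rng.choice(_BASES)))
        else:
            allele = Allele(DELETION, int(rng.choice(deletion_sizes)))
        if allele.label not in exclude:
            return allele
    raise RuntimeError("could not draw a distinct mutant allele")


def _random_genotype(zygosity: str, rng: np.random.Generator) -> Genotype:
    if zygosity == "wild_type":
        return Genotype((REFERENCE_ALLELE, REFERENCE_ALLELE))
    if zygosity == "homozygous":
        m = _random_mutant_allele(rng)
        return Genotype((m, m))
    if zygosity == "heterozygous":
        m = _random_mutant_allele(rng)
        return Genotype((REFERENCE_ALLELE, m))
    if zygosity == "bi_allelic":
        m1 = _random_mutant_allele(rng)
        m2 = _random_mutant_allele(rng, exclude=frozenset({m1.label}))
        return Genotype((m1, m2))
    if zygosity == "chimeric":
        n_mut = int(rng.integers(2, 5))
        alleles: list[Allele] = []
        labels: set[str] = set()
        for _ in range(n_mut):
            m = _random_mutant_allele(rng, exclude=frozenset(labels))
            alleles.append(m)
            labels.add(m.label)
        fracs = rng.uniform(CHIMERA_SECTOR_LO, CHIMERA_SECTOR_HI, size=n_mut)
        remainder = 1.0 - fracs.sum()
        if remainder > 1e-9:
            alleles.append(REFERENCE_ALLELE)
            fracs = np.append(fracs, remainder)
        else:  # renormalise the mutant sectors
            fracs = fracs / fracs.sum()
        return Genotype(tuple(alleles), tuple(float(f) for f in fracs))
    raise ValueError(f"unknown zygosity class: {zygosity!r}")


def generate_cohort(
    design: Mapping[str, Mapping[str, int]],
    sites: Mapping[str, TargetSite],
    seed: int = 0,
    read_params: Optional[ReadSimParams] = None,
    generation: str = "T0",
) -> tuple[list[TruthPlant], dict[tuple[str, str], list[SimulatedRead]], pd.DataFrame]:
    """Generate a cohort of plants with designed zygosity-class counts per locus.

    ``design`` maps locus id -> {class name -> count}.  Canonical spectra are
    used per class (homozygous {m: 1}; heterozygous {WT: 1/2, m: 1/2};
    bi-allelic {m1: 1/2, m2: 1/2}; chimeric sectors in [0.05, 0.30]).  Returns
    the plants, per-(plant, locus) simulated reads, and a truth table suitable
    for scoring.  Loci with fewer designed plants than the cohort size are
    padded with wild type.
    """
    if not design or all(
        sum(counts.values()) == 0 for counts in design.values()
    ):
        raise ValueError("empty cohort design")
    for locus in design:
        if locus not in sites:
            raise ValueError(f"no target site supplied for locus {locus!r}")

    rng = np.random.default_rng(seed)
    n_plants = max(sum(counts.values()) for counts in design.values())

    per_locus_classes: dict[str, list[str]] = {}
    for locus, counts in design.items():
        classes: list[str] = []
        for cls, n in counts.items():
            if cls not in ZYGOSITY_CLASSES:
                raise ValueError(f"unknown zygosity class {cls!r}")
            if n < 0:
                raise ValueError("design counts must be >= 0")
            classes.extend([cls] * n)
        classes.extend(["wild_type"] * (n_plants - len(classes)))
        per_locus_classes[locus] = classes

    plants: list[TruthPlant] = []
    reads: dict[tuple[str, str], list[SimulatedRead]] = {}
    rows = []
    for i in range(n_plants):
        plant_id = f"P{i + 1:04d}"
        genotypes = {
            locus: _random_genotype(per_locus_classes[locus][i], rng)
            for locus in design
        }
        plant = TruthPlant(plant_id, generation, genotypes, cas9_present=True)
        plants.append(plant)
        for locus, genotype in genotypes.items():
            if read_params is not None:
                locus_key = zlib.crc32(locus.encode()) % 2**16
                sub_seed = int(
                    np.random.SeedSequence([read_params.seed, i, locus_key])
                    .generate_state(1)[0]
                    % 2**31
                )
                plant_params = ReadSimParams(
                    n_reads=read_params.n_reads,
                    error_rate=read_params.error_rate,
                    read_length=read_params.read_length,
                    seed=sub_seed,
                )
                reads[(plant_id, locus)] = simulate_reads(
                    plant, sites[locus], plant_params, locus=locus
                )
            rows.append(
                {
                    "plant_id": plant_id,
                    "generation": generation,
                    "parent_id": "",
                    "locus": locus,
                    "genotype": genotype.label,
                    "zygosity": zygosity_of(genotype),
                    "cas9": True,
                    "unexpected": False,
                }
            )
    truth = pd.DataFrame(rows)
    return plants, reads, truth
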