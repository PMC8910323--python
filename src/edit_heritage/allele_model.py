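"""Coordinate geometry and allele/genotype representation for Cas9 target sites.

SpCas9 cleaves bluntly 3 bp upstream (5') of the NGG PAM.  All coordinates are
0-based, half-open offsets on the amplicon *plus* strand; minus-strand guides
are handled by the strand-symmetric geometry.  Alleles are the indel
signatures produced by NHEJ repair: an insertion (size + inserted bases) or a
deletion (size), positioned relative to the cut.  Genotype labels use the
field's slash dialect, e.g. ``-4 bp/-4 bp`` or ``+1 bp(T)/-6 bp/-5 bp/-4 bp``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

PROTOSPACER_LEN = 20
PAM_LEN = 3
CUT_DISTANCE_FROM_PAM = 3  # blunt cut 3 bp upstream of the PAM

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class InvalidSiteError(ValueError):
    """Target-site geometry violates the protospacer/PAM/cut invariants."""


class AlleleParseError(ValueError):
    """A genotype or allele label is not in the recognised dialect."""


# --------------------------------------------------------------------------
# Alleles
# --------------------------------------------------------------------------

REFERENCE_KIND = "reference"
INSERTION = "insertion"
DELETION = "deletion"

_WT_TOKENS = {"wt", "no mutation", "wild type", "wild-type", "wildtype"}

# "+1 bp(T)", "+1 bp (T)", "-4 bp", "−4 bp", "+ 1bp"
_LABEL_RE = re.compile(
    r"^(?P<sign>[+\-−–])\s*(?P<size>\d+)\s*bp\s*"
    r"(?:\(\s*(?P<bases>[ACGTacgt]+)\s*\))?$"
)


@dataclass(frozen=True, order=True)
class Allele:
    """One indel (or reference) signature at a target site.

    ``inserted_seq`` may be empty for an insertion whose bases were not
    reported (labels like ``+1 bp``); such alleles carry a size but cannot be
    applied to a sequence.  ``start_offset`` is the signed bp position of the
    event start relative to the cut (0 = at the cut).
    """

    kind: str
    size: int = 0
    inserted_seq: str = ""
    start_offset: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (REFERENCE_KIND, INSERTION, DELETION):
            raise ValueError(f"unknown allele kind: {self.kind!r}")
        if self.kind == REFERENCE_KIND:
            if self.size != 0 or self.inserted_seq:
                raise ValueError("reference allele must have size 0 and no bases")
        elif self.size <= 0:
            raise ValueError(f"{self.kind} requires size > 0")
        if self.kind == INSERTION:
            if self.inserted_seq and len(self.inserted_seq) != self.size:
                raise ValueError("inserted_seq length must equal insertion size")
            object.__setattr__(self, "inserted_seq", self.inserted_seq.upper())
        elif self.inserted_seq:
            raise ValueError(f"{self.kind} must not carry inserted bases")

    @property
    def is_mutant(self) -> bool:
        return self.kind != REFERENCE_KIND

    @property
    def label(self) -> str:
        return format_allele_label(self)


REFERENCE_ALLELE = Allele(REFERENCE_KIND)


def format_allele_label(allele: Allele) -> str:
    """Render an allele in the slash-dialect (ASCII signs)."""
    if allele.kind == REFERENCE_KIND:
        return "WT"
    if allele.kind == INSERTION:
        if allele.inserted_seq:
            return f"+{allele.size} bp({allele.inserted_seq})"
        return f"+{allele.size} bp"
    return f"-{allele.size} bp"


def parse_allele_label(label: str) -> Allele:
    """Parse one allele label: ``WT`` / ``No mutation`` / ``+N bp(S)`` / ``-N bp``.

    Both ASCII ``-`` and Unicode minus are accepted.  Position information is
    never carried by the dialect, so ``start_offset`` defaults to 0 (at the
    cut).
    """
    token = label.strip()
    if not token:
        raise AlleleParseError("empty allele label")
    if token.lower() in _WT_TOKENS:
        return REFERENCE_ALLELE
    m = _LABEL_RE.match(token)
    if m is None:
        raise AlleleParseError(f"unrecognised allele label: {label!r}")
    size = int(m.group("size"))
    if size == 0:
        raise AlleleParseError(f"zero-size indel in label: {label!r}")
    bases = (m.group("bases") or "").upper()
    if m.group("sign") == "+":
        if bases and len(bases) != size:
            raise AlleleParseError(
                f"inserted bases {bases!r} do not match size {size} in {label!r}"
            )
        return Allele(INSERTION, size, bases)
    if bases:
        raise AlleleParseError(f"deletion label cannot carry bases: {label!r}")
    return Allele(DELETION, size)


# --------------------------------------------------------------------------
# Genotypes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Genotype:
    """A diploid allele pair, or a chimeric mixture of >= 3 allelic states.

    For chimeric genotypes ``fractions`` holds per-allele sector fractions
    (allele-frequency scale); they may be None when unknown (e.g. parsed from
    a table label).
    """

    alleles: tuple[Allele, ...]
    fractions: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if len(self.alleles) < 2:
            raise ValueError("genotype needs at least two allelic states")
        if self.fractions is not None:
            if len(self.fractions) != len(self.alleles):
                raise ValueError("one fraction per allele required")
            if any(f <= 0 or f > 1 for f in self.fractions):
                raise ValueError("fractions must lie in (0, 1]")
            if sum(self.fractions) > 1 + 1e-9:
                raise ValueError("fractions must sum to <= 1")

    @property
    def is_chimeric(self) -> bool:
        return len(self.alleles) > 2

    @property
    def allele_labels(self) -> tuple[str, ...]:
        return tuple(a.label for a in self.alleles)

    @property
    def label(self) -> str:
        return format_genotype_label(self)

    def normalized_fractions(self) -> tuple[float, ...]:
        """Allele sampling weights: stated fractions (renormalised) or uniform."""
        if self.fractions is None:
            n = len(self.alleles)
            return tuple(1.0 / n for _ in range(n))
        total = sum(self.fractions)
        return tuple(f / total for f in self.fractions)


def format_genotype_label(genotype: Genotype) -> str:
    if not genotype.is_chimeric and all(
        a == REFERENCE_ALLELE for a in genotype.alleles
    ):
        return "No mutation"
    return "/".join(a.label for a in genotype.alleles)


def parse_genotype_label(label: str) -> Genotype:
    """Parse a slash-separated genotype label.

    One label must be a wild-type token and yields the reference/reference
    diploid; two labels yield a diploid pair; three or more yield a chimeric
    genotype with unspecified sector fractions.
    """
    if not label or not label.strip():
        raise AlleleParseError("empty genotype label")
    parts = [p for p in (s.strip() for s in label.split("/")) if p]
    if not parts:
        raise AlleleParseError(f"no allele labels in genotype: {label!r}")
    alleles = tuple(parse_allele_label(p) for p in parts)
    if len(alleles) == 1:
        if alleles[0].is_mutant:
            raise AlleleParseError(
                f"single-allele genotype must be wild type: {label!r}"
            )
        return Genotype((REFERENCE_ALLELE, REFERENCE_ALLELE))
    return Genotype(alleles)


def zygosity_of(genotype: Genotype) -> str:
    """Map a genotype to its zygosity class name."""
    if genotype.is_chimeric:
        return "chimeric"
    a, b = genotype.alleles
    if not a.is_mutant and not b.is_mutant:
        return "wild_type"
    if not a.is_mutant or not b.is_mutant:
        return "heterozygous"
    return "homozygous" if a.label == b.label else "bi_allelic"


# --------------------------------------------------------------------------
# Target sites
# --------------------------------------------------------------------------


def expected_cut_offset(pam_start: int, strand: str) -> int:
    """Offset of the first base 3' of the blunt cut, on the amplicon plus strand."""
    if strand == "plus":
        return pam_start - CUT_DISTANCE_FROM_PAM
    if strand == "minus":
        # strand-symmetric: PAM is CCN on the plus strand, protospacer 3' of it
        return pam_start + PAM_LEN + CUT_DISTANCE_FROM_PAM
    raise InvalidSiteError(f"unknown strand: {strand!r}")


@dataclass(frozen=True)
class TargetSite:
    """Reference amplicon plus protospacer/PAM geometry for one guide."""

    site_id: str
    reference: str
    protospacer_start: int
    protospacer_end: int
    pam_start: int
    strand: str
    cut_offset: int = field(default=-1)

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference", self.reference.upper())
        if self.cut_offset == -1:
            object.__setattr__(
                self, "cut_offset", expected_cut_offset(self.pam_start, self.strand)
            )
        self.validate()

    def validate(self) -> None:
        ref = self.reference
        L = len(ref)
        if self.strand not in ("plus", "minus"):
            raise InvalidSiteError(f"unknown strand: {self.strand!r}")
        if self.protospacer_end - self.protospacer_start != PROTOSPACER_LEN:
            raise InvalidSiteError("protospacer must be 20 nt")
        offsets = (
            self.protospacer_start,
            self.protospacer_end - 1,
            self.pam_start,
            self.pam_start + PAM_LEN - 1,
            self.cut_offset,
        )
        if any(o < 0 or o >= L for o in offsets):
            raise InvalidSiteError("site offsets fall outside the amplicon")
        pam = ref[self.pam_start : self.pam_start + PAM_LEN]
        if self.strand == "plus":
            if self.pam_start != self.protospacer_end:
                raise InvalidSiteError("plus-strand PAM must abut the protospacer 3' end")
            pam_on_guide = pam
        else:
            if self.protospacer_start != self.pam_start + PAM_LEN:
                raise InvalidSiteError("minus-strand PAM must abut the protospacer")
            pam_on_guide = reverse_complement(pam)
        if not (len(pam_on_guide) == PAM_LEN and pam_on_guide.endswith("GG")):
            raise InvalidSiteError(
                f"PAM {pam_on_guide!r} is not NGG on the protospacer strand"
            )
        if self.cut_offset != expected_cut_offset(self.pam_start, self.strand):
            raise InvalidSiteError("cut_offset inconsistent with PAM position")

    @property
    def protospacer(self) -> str:
        """Protospacer sequence, 5'->3' on the guide (protospacer) strand."""
        window = self.reference[self.protospacer_start : self.protospacer_end]
        return window if self.strand == "plus" else reverse_complement(window)


def cut_site(site: TargetSite) -> int:
    """Return the cut offset (first base 3' of the blunt cut, plus strand).

    Depends only on the PAM position and strand, never on base content
    outside the PAM; raises :class:`InvalidSiteError` for malformed sites.
    """
    site.validate()
    return site.cut_offset


def apply_allele(site: TargetSite, allele: Allele) -> str:
    """Apply an indel allele to the reference amplicon, returning the mutant sequence."""
    ref = site.reference
    if allele.kind == REFERENCE_KIND:
        return ref
    pos = site.cut_offset + allele.start_offset
    if allele.kind == INSERTION:
        if not allele.inserted_seq:
            raise ValueError(
                f"cannot apply insertion with unspecified bases: {allele.label}"
            )
        if pos < 0 or pos > len(ref):
            raise ValueError("insertion position outside the amplicon")
        return ref[:pos] + allele.inserted_seq + ref[pos:]
    if pos < 0 or pos + allele.size > len(ref):
        raise ValueError("deletion extends past the amplicon end")
    return ref[:pos] + ref[pos + allele.size :]


# --------------------------------------------------------------------------
# Serialization: FASTA amplicon + JSON sidecar
# --------------------------------------------------------------------------


def write_target(site: TargetSite, fasta_path: Path | str, json_path: Path | str) -> None:
    fasta_path, json_path = Path(fasta_path), Path(json_path)
    with open(fasta_path, "w") as fh:
        fh.write(f">{site.site_id}\n")
        for i in range(0, len(site.reference), 70):
            fh.write(site.reference[i : i + 70] + "\n")
    meta = {
        "site_id": site.site_id,
        "protospacer_start": site.protospacer_start,
        "protospacer_end": site.protospacer_end,
        "pam_start": site.pam_start,
        "strand": site.strand,
        "cut_offset": site.cut_offset,
    }
    json_path.write_text(json.dumps(meta, indent=2) + "\n")


def read_target(fasta_path: Path | str, json_path: Path | str) -> TargetSite:
    from Bio import SeqIO

    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    meta = json.loads(Path(json_path).read_text())
    return TargetSite(
        site_id=meta["site_id"],
        reference=str(record.seq),
        protospacer_start=meta["protospacer_start"],
        protospacer_end=meta["protospacer_end"],
        pam_start=meta["pam_start"],
        strand=meta["strand"],
        cut_offset=meta["cut_offset"],
    )
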