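"""Allele calling from amplicon reads by global alignment to the reference.

Each read is aligned to a reference window around the cut site with an affine
gap model (match +2, mismatch -2, gap of length k scores -(6 + k)); read ends
falling outside the window are free.  Indel events are extracted in amplicon
coordinates and normalised by shifting ambiguous gaps toward the PAM-proximal
side, so one biological event always yields one signature.  A read calls an
allele only when it carries exactly one contiguous indel within a window of
the cut (default +/- 10 bp); reads with scattered or off-target indels are
discarded with a reason.  Per-allele read counts become a frequency spectrum
after a noise floor (default 5%, the lower bound of the chimera band) removes
sporadic error-driven signatures.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import Align

from .allele_model import (
    DELETION,
    INSERTION,
    Allele,
    REFERENCE_ALLELE,
    TargetSite,
    reverse_complement,
)
from .synthetic_data import SimulatedRead

MATCH_SCORE = 2.0
MISMATCH_SCORE = -2.0
GAP_OPEN = 6.0  # gap of length k costs GAP_OPEN + k * GAP_EXTEND
GAP_EXTEND = 1.0

DEFAULT_CALL_WINDOW = 10
DEFAULT_MIN_FREQ = 0.05
REF_WINDOW_MARGIN = 30

DISCARD_MULTIPLE_INDELS = "multiple_disjoint_indels"
DISCARD_INDEL_OUTSIDE_WINDOW = "indel_outside_window"


class EmptySpectrumError(ValueError):
    """No reads survived allele calling for this plant-locus."""


@dataclass(frozen=True)
class IndelEvent:
    """One indel in amplicon (plus-strand) coordinates."""

    offset: int  # reference offset where the event begins
    kind: str  # insertion | deletion
    size: int
    inserted: str = ""


@dataclass
class AlignmentResult:
    aligned_ref: str
    aligned_read: str
    score: float
    events: list[IndelEvent]
    ref_start: int  # amplicon offset of the first aligned reference base
    reverse_complemented: bool = False


@dataclass
class AlleleSpectrum:
    """Observed per-locus allele frequencies supported by retained reads."""

    locus_id: str
    frequencies: dict[Allele, float]
    n_reads_used: int
    n_reads_discarded: int

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if self.frequencies and abs(total - 1.0) > 1e-9:
            raise ValueError(f"spectrum frequencies sum to {total}, expected 1")
        if any(f <= 0 for f in self.frequencies.values()):
            raise ValueError("spectrum frequencies must be positive")

    def by_label(self) -> dict[str, float]:
        """Frequencies aggregated at the label level (position-insensitive)."""
        out: dict[str, float] = {}
        for allele, freq in self.frequencies.items():
            out[allele.label] = out.get(allele.label, 0.0) + freq
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"locus": self.locus_id, "allele": a.label, "frequency": f}
            for a, f in sorted(self.frequencies.items(), key=lambda kv: -kv[1])
        ]
        return pd.DataFrame(rows)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    # biopython convention: first gap position scores open, the rest extend
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    # reads cover only part of the reference window: free end gaps in the read
    aligner.open_left_deletion_score = 0
    aligner.extend_left_deletion_score = 0
    aligner.open_right_deletion_score = 0
    aligner.extend_right_deletion_score = 0
    return aligner


_ALIGNER = _make_aligner()


def alignment_score(reference: str, read: str) -> float:
    """Score of the best global alignment of ``read`` against ``reference``.

    Uses the module's scoring scheme (match +2, mismatch -2, gap of length k
    scores -(6 + k)) with free end gaps in the read, exactly as allele calling
    does.
    """
    return float(_ALIGNER.align(reference.upper(), read.upper()).score)


def _reference_window(site: TargetSite, read_length: int) -> tuple[str, int]:
    half = read_length // 2 + REF_WINDOW_MARGIN
    start = max(0, site.cut_offset - half)
    end = min(len(site.reference), site.cut_offset + half)
    return site.reference[start:end], start


def _events_from_alignment(
    aligned_blocks, ref_start: int, ref: str, read: str
) -> list[IndelEvent]:
    """Extract internal indels from biopython's aligned-block coordinates."""
    target_blocks, query_blocks = aligned_blocks
    events: list[IndelEvent] = []
    for i in range(1, len(target_blocks)):
        t_gap = int(target_blocks[i][0] - target_blocks[i - 1][1])
        q_gap = int(query_blocks[i][0] - query_blocks[i - 1][1])
        offset = ref_start + int(target_blocks[i - 1][1])
        if t_gap and not q_gap:
            events.append(IndelEvent(offset, DELETION, t_gap))
        elif q_gap and not t_gap:
            ins = read[int(query_blocks[i - 1][1]) : int(query_blocks[i][0])]
            events.append(IndelEvent(offset, INSERTION, q_gap, ins))
        elif t_gap and q_gap:
            # adjacent gap columns in both sequences; report both parts
            events.append(IndelEvent(offset, DELETION, t_gap))
            events.append(
                IndelEvent(
                    offset + t_gap,
                    INSERTION,
                    q_gap,
                    read[int(query_blocks[i - 1][1]) : int(query_blocks[i][0])],
                )
            )
    return events


def _shift_event(event: IndelEvent, ref: str, direction: int) -> IndelEvent:
    """Slide an indel through equal-context sequence toward the PAM side."""
    offset, size, ins = event.offset, event.size, event.inserted
    if event.kind == DELETION:
        if direction > 0:
            while offset + size < len(ref) and ref[offset] == ref[offset + size]:
                offset += 1
        else:
            while offset > 0 and ref[offset - 1] == ref[offset + size - 1]:
                offset -= 1
        return IndelEvent(offset, DELETION, size)
    if direction > 0:
        while offset < len(ref) and ins and ins[0] == ref[offset]:
            ins = ins[1:] + ref[offset]
            offset += 1
    else:
        while offset > 0 and ins and ins[-1] == ref[offset - 1]:
            ins = ref[offset - 1] + ins[:-1]
            offset -= 1
    return IndelEvent(offset, INSERTION, size, ins)


def align_read(
    read: str | SimulatedRead, site: TargetSite, window_ref: Optional[tuple[str, int]] = None
) -> AlignmentResult:
    """Globally align one read to the reference window around the cut.

    Orientation is auto-detected by comparing forward and reverse-complement
    scores.  Indel events are reported in amplicon coordinates, normalised
    toward the PAM-proximal side.
    """
    seq = read.sequence if isinstance(read, SimulatedRead) else read
    if not seq:
        raise ValueError("cannot align a zero-length read")
    seq = seq.upper()
    if window_ref is None:
        window_ref = _reference_window(site, len(seq))
    ref, ref_start = window_ref

    fwd = _ALIGNER.align(ref, seq)
    max_possible = MATCH_SCORE * len(seq)
    revcomp = False
    best = fwd
    best_seq = seq
    # skip the reverse-complement attempt when the forward score is already
    # near-perfect; otherwise compare both orientations
    if fwd.score < 0.9 * max_possible:
        rc_seq = reverse_complement(seq)
        rev = _ALIGNER.align(ref, rc_seq)
        if rev.score > fwd.score:
            best, best_seq, revcomp = rev, rc_seq, True

    alignment = best[0]
    events = _events_from_alignment(alignment.aligned, ref_start, ref, best_seq)
    direction = 1 if site.pam_start >= site.cut_offset else -1
    full_ref = site.reference
    events = [_shift_event(e, full_ref, direction) for e in events]
    return AlignmentResult(
        aligned_ref=alignment[0],
        aligned_read=alignment[1],
        score=float(best.score),
        events=events,
        ref_start=ref_start,
        reverse_complemented=revcomp,
    )


def call_read_allele(
    aln: AlignmentResult, site: TargetSite, window: int = DEFAULT_CALL_WINDOW
) -> tuple[Optional[Allele], Optional[str]]:
    """Call one allele from an aligned read, or discard it with a reason.

    Returns ``(allele, None)`` on success and ``(None, reason)`` on discard.
    A read with no indels near the cut is a reference-allele observation.
    """
    cut = site.cut_offset
    lo, hi = cut - window, cut + window

    def in_window(ev: IndelEvent) -> bool:
        if ev.kind == DELETION:
            return ev.offset <= hi and ev.offset + ev.size >= lo
        return lo <= ev.offset <= hi

    if not aln.events:
        return REFERENCE_ALLELE, None
    inside = [e for e in aln.events if in_window(e)]
    outside = [e for e in aln.events if not in_window(e)]
    if len(inside) == 1 and not outside:
        ev = inside[0]
        if ev.kind == INSERTION:
            return Allele(INSERTION, ev.size, ev.inserted, ev.offset - cut), None
        return Allele(DELETION, ev.size, "", ev.offset - cut), None
    if not inside:
        return None, DISCARD_INDEL_OUTSIDE_WINDOW
    return None, DISCARD_MULTIPLE_INDELS


def build_spectrum(
    reads: Iterable[str | SimulatedRead],
    site: TargetSite,
    min_freq: float = DEFAULT_MIN_FREQ,
    window: int = DEFAULT_CALL_WINDOW,
    locus_id: Optional[str] = None,
) -> AlleleSpectrum:
    """Build the observed allele spectrum for one plant-locus read set.

    Duplicate reads are collapsed before alignment, so the result depends only
    on read counts, never on read order.  Alleles below ``min_freq`` of the
    retained reads are dropped and the remaining mass renormalised.
    """
    seqs = [r.sequence if isinstance(r, SimulatedRead) else r for r in reads]
    if not seqs:
        raise EmptySpectrumError("no reads supplied")
    counts = Counter(s.upper() for s in seqs)

    window_ref = _reference_window(site, len(seqs[0]))
    allele_counts: Counter[Allele] = Counter()
    n_discarded = 0
    for seq in sorted(counts):  # sorted for order-independence
        n = counts[seq]
        aln = align_read(seq, site, window_ref=window_ref)
        allele, _reason = call_read_allele(aln, site, window=window)
        if allele is None:
            n_discarded += n
        else:
            allele_counts[allele] += n

    n_used = sum(allele_counts.values())
    if n_used == 0:
        raise EmptySpectrumError("all reads were discarded")
    raw = {a: c / n_used for a, c in allele_counts.items()}
    kept = {a: f for a, f in raw.items() if f >= min_freq}
    if not kept:
        raise EmptySpectrumError("no allele above the noise floor")
    total = sum(kept.values())
    freqs = {a: f / total for a, f in kept.items()}
    return AlleleSpectrum(
        locus_id=locus_id or site.site_id,
        frequencies=freqs,
        n_reads_used=n_used,
        n_reads_discarded=n_discarded,
    )


def write_spectrum_tsv(spectra: Sequence[tuple[str, AlleleSpectrum]], path: Path | str) -> None:
    """Write per-plant spectra as TSV: plant_id, locus, allele, frequency."""
    with open(path, "w") as fh:
        fh.write("plant_id\tlocus\tallele\tfrequency\tn_reads_used\tn_reads_discarded\n")
        for plant_id, spec in spectra:
            for allele, freq in sorted(
                spec.frequencies.items(), key=lambda kv: -kv[1]
            ):
                fh.write(
                    f"{plant_id}\t{spec.locus_id}\t{allele.label}\t{freq:.6f}"
                    f"\t{spec.n_reads_used}\t{spec.n_reads_discarded}\n"
                )
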