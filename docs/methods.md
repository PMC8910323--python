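# Methods

This document records the model, the numerical conventions and the design
decisions behind the package, in enough detail to re-derive every computed
quantity.

## 1. Coordinate system and cut-site geometry

All positions are 0-based, half-open offsets into the plus strand of the
amplicon. A target site stores the protospacer interval, the PAM start and
the guide strand.

Cas9 cuts bluntly 3 bp upstream of the NGG PAM, on the protospacer side:

- **Plus-strand guide** (PAM at `[pam_start, pam_start+3)`, protospacer at
  `[pam_start-20, pam_start)`): `cut_offset = pam_start - 3`.
- **Minus-strand guide** (PAM stored as CCN on the plus strand at
  `[pam_start, pam_start+3)`, protospacer at `[pam_start+3, pam_start+23)`):
  `cut_offset = pam_start + 6`.

The minus-strand rule is derived by reverse-complementing the amplicon,
applying the plus-strand rule in the guide's frame, and mapping the cut
junction back — the tests check exactly this equivalence.

## 2. Allele and genotype model

An allele is reference, an insertion (size + optionally the inserted bases)
or a deletion (size), with an offset relative to the cut. Labels follow the
study's dialect: `WT` / `No mutation`, `+N bp(S)`, `+N bp`, `−N bp` (both
ASCII `-` and Unicode `−`/`–` are parsed; ASCII is emitted). Label equality
is the unit of identity everywhere downstream: `+1 bp(T)` and `+1 bp(G)` are
different alleles, which is what lets the retention analysis catch a progeny
plant that swapped its parent's `+1 bp(T)` for a de novo `+1 bp(G)`.

A genotype is a tuple of alleles: exactly two for a diploid, three or more
(with sector fractions summing to ≤ 1, remainder wild type) for a chimera.
A single `+N bp` label with no bases is parseable — the printed tables use
it — but cannot be applied to a sequence, and `apply_allele` rejects it.

## 3. Read simulation

Each read is drawn from one allelic state (probability ½ per chromosome for
a diploid; sector fractions for a chimera), the mutant amplicon is computed,
a `read_length` window centred on the cut is extracted, and i.i.d.
substitution errors are applied at `error_rate` (default 0.001, max 0.05).
No indel errors by default, keeping the caller's indel channel unambiguous.
Base qualities are constant Phred 30 and never used.

Target amplicons embed a 20-nt protospacer with an **exact** G/C count of
`round(20 * gc)` (so `gc` must be a multiple of 0.05) plus an NGG PAM,
emulating the study's 30% and 60% GC guides; the default pipeline places the
guide on the minus strand, matching the study's first-exon reverse-strand
targets.

All randomness flows from integer seeds through `numpy.random.default_rng`
and `SeedSequence` spawning (locus names are mixed in via `zlib.crc32`,
never Python's salted `hash`), so every output is byte-identical per seed.

## 4. Allele calling

Reads are aligned globally to a reference window around the cut
(half read length + 30 bp each side) with an affine gap model:

- match +2, mismatch −2, a gap of length *k* costs 6 + *k*
  (open −7, extend −1 in biopython's convention);
- read end-gaps are free, since a read covers only part of the window;
- orientation is auto-detected by comparing forward and reverse-complement
  scores (skipped when the forward score is already ≥ 90% of the maximum).

The scoring scheme is verified against an independently written three-state
Gotoh dynamic program (`tests/dp_oracle.py`) over 1,000 random instances.

Indel events are normalised by sliding them through equal-context sequence
toward the PAM-proximal side, so one biological event yields one signature
regardless of where the aligner happened to place the gap. A read calls an
allele only when it carries exactly one contiguous indel overlapping a
±10 bp window around the cut; reads with scattered or off-window indels are
discarded with a recorded reason. A read with no indels is a reference
observation.

Per-allele counts become a frequency spectrum; alleles below the 5% noise
floor (the lower edge of the chimera band) are dropped and the rest
renormalised. Duplicate reads are collapsed before alignment, which makes
the spectrum independent of read order and fast at depth 2,000
(substitution errors at 0.1% leave ~280 distinct sequences per plant).

## 5. Zygosity classification

Rules fire in fixed precedence on label-aggregated frequencies:

| class | rule | defaults |
|---|---|---|
| homozygous | one mutation above `homo_min` | > 0.98 |
| wild type | all mutations below `chimera_lo` | < 0.05 |
| bi-allelic | exactly 2 mutations in the band, reference ≤ `chimera_lo` | band [0.30, 0.60] |
| heterozygous | exactly 1 mutation in the band | band [0.30, 0.60] |
| chimeric | catch-all | — |

The band is the 40–50% heterozygous/bi-allelic range widened by a tolerance
τ = 0.10 on each side to absorb binomial sampling noise at realistic depth.
Two deliberate conventions:

- The bi-allelic rule uses **≤** `chimera_lo` for residual reference reads
  (a spectrum with WT exactly at the 5% floor is still bi-allelic).
- Spectra that fit no rule — e.g. a lone mutation at 70%, or two in-band
  mutations with 20% residual WT — fall to chimeric. The catch-all means a
  chimeric call can carry a single mutant allele.

On canonical spectra the classifier recovers every class exactly; on
simulated reads (2,000 reads, 0.1% error, 510 plants, 102 per class) the
acceptance test requires ≥ 99% per-class recovery and the observed confusion
matrix is diagonal.

## 6. Inheritance simulation

Selfing of one parent, per progeny plant:

1. **Transgene**: carried with probability 0.75 (`mendelian_3_1`, hemizygous
   single-locus insertion) or 0.5 (`observed_1_1`, the segregation actually
   observed in the study's T2 panel). Cas9-free parents transmit nothing.
2. **Gametes**: two alleles per locus, uniform over a diploid pair or in
   proportion to sector fractions for a chimeric germline.
3. **De novo editing** (only when Cas9 is present): each transmitted
   wild-type allele is edited with probability `p_edit` (default 0.5). An
   edit is late with probability `p_late` (default 0.5): a late edit
   converts only a sector — drawn uniform on [0.05, 0.30] of allele
   frequency — producing a chimera; an early edit replaces the allele
   outright. De novo indels are +1 bp with a random base or a 1–11 bp
   deletion (uniform by default).

Edited alleles never re-mutate. This single assumption reproduces the
study's central observation: homozygous and bi-allelic parents breed
perfectly true, while wild-type and heterozygous parents yield chimeras and
novel alleles whenever Cas9 is retained. With the defaults, ~45% of Cas9
carriers from a WT/WT selfing are chimeric, inside the range the study's
WT-parent lines show (6/11 and 3/8). With `p_edit = 0` the simulator is
purely Mendelian and recovers 1:2:1 at n = 10,000 (chi-square GOF
p ≫ 0.001).

## 7. Statistics and rounding

- **Percentages** are kept as exact `Fraction`s and formatted with an
  explicit convention, because the study's tables mix two: `truncate`
  (ROUND_DOWN: 56/248 → 22.5, 51/248 → 20.56, 81.875 → 81.8) and `round`
  (half-up: 5/11 → 45.5, 77.386 → 77.4). `reports.study_summary` pins the
  convention per printed cell.
- **Retention**: progeny are bucketed as `expected_<class>` (non-chimeric,
  allele labels a subset of the parent's), `chimeric`, or `unexpected`
  (novel alleles). Buckets always sum to the progeny total.
- **Segregation ratios**: Pearson chi-square statistic; for totals ≤ 30 the
  p-value is computed by exact multinomial enumeration (all compositions
  with probability ≤ the observed outcome's), since typical line sizes
  (8–11 progeny) are far below asymptotic validity. The enumeration agrees
  with `scipy.stats.binomtest` in the two-class case.
- **Transgene fraction**: exact binomial tests against both nulls, 1:1 and
  3:1. The study's 10/20 T2 carriers are consistent with 1:1 (p = 1.0) and
  not with 3:1 (p < 0.05).

## 8. Known limitations and open points

- The study reports one average ("53%" wild-type-parent retention) that no
  rounding convention reproduces from the printed per-line values
  ((45.5 + 62.5)/2 = 54.0); it is excluded from the recomputed summary.
- The caller assumes one contiguous indel per read near the cut; very large
  deletions (the study observed one of 113 bp) exceed the default read
  window and are out of scope for the read-level layer, though the allele
  label parses and flows through the statistics.
- Substitution-only sequencing error is a deliberate simplification; an
  indel error channel would require a confidence model in the caller.
- Chimera sector fractions are modelled directly on the allele-frequency
  scale, not through an explicit cell-lineage model.
- The classifier leaves the 30–40% and 50–98% frequency ranges unassigned
  by any specific rule; spectra there are chimeric by fall-through, which
  matches how irregular ratios were interpreted in the study.
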