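# edit-heritage

Analysis toolkit for the inheritance of CRISPR-Cas9-induced mutations in
plants, built around a published editing study of the *NbFucT1* and *NbXylT1*
glycosyltransferase loci in *Nicotiana benthamiana*. The package covers the
full path from amplicon reads to cross-generation statistics:

- **Allele model** — indel alleles anchored at the Cas9 blunt cut (3 bp
  upstream of the NGG PAM), diploid and chimeric genotypes, and the label
  dialect used in the study's tables (`WT`, `+1 bp(T)`, `-4 bp`, …).
- **Synthetic data** — deterministic generation of target amplicons with
  exact protospacer GC content, truth cohorts of known zygosity, and
  FASTQ reads with substitution errors. The study never deposited raw reads,
  so the simulator stands in for the read level.
- **Amplicon caller** — affine-gap global alignment of reads to the target
  (match +2, mismatch −2, gap of length *k* costs 6 + *k*; free read
  end-gaps), PAM-directed indel normalisation, and per-plant allele
  frequency spectra with a 5% noise floor.
- **Zygosity classifier** — the deep-sequencing threshold rules: homozygous
  (one mutation > 98%), bi-allelic / heterozygous (mutations in the
  40–50% band, widened by a ±10-point tolerance), wild type (nothing at the
  5% floor) and chimeric as the catch-all.
- **Inheritance simulator** — selfed-progeny transmission with Mendelian
  gamete sampling, 3:1 or 1:1 Cas9 transgene segregation, and de novo
  editing of transmitted wild-type alleles (early edits replace the allele;
  late edits create a chimera). Edited alleles never re-mutate, so fully
  mutant parents breed true.
- **Segregation statistics** — mutation-rate accounting, zygosity spectra,
  per-line genotype retention, exact multinomial goodness-of-fit tests for
  segregation ratios, and exact binomial tests for transgene fractions.
  Percentages carry an explicit rounding convention (`round` half-up vs
  `truncate`) because the study's tables mix both.

The study's genotype tables (T0 mutation tallies over 248 regenerants, the
17-line T0 panel, both T0→T1 transmission tables, and the Ta161 T1→T2 panel)
ship as TSV fixtures in `edit_heritage/data/` and are the primary ground
truth for the statistics layer.

## Quick start

Reproduce every headline percentage of the study from the packaged tables:

```console
$ edit-heritage reproduce-study
quantity                      computed  printed  status
fuct1_mutation_rate_pct           22.5     22.5  ok
xylt1_mutation_rate_pct             25       25  ok
both_loci_mutation_rate_pct      20.56    20.56  ok
dual_mutation_proportion_pct        76       76  ok
t0_fuct1_wild_type_pct            17.6     17.6  ok
t0_fuct1_homozygous_pct           52.9     52.9  ok
...
```

The command exits nonzero if any recomputed value disagrees with the printed
one.

Run the full synthetic pipeline — simulate a cohort, call alleles from the
FASTQ reads, classify zygosity and score against the truth table:

```sh
edit-heritage simulate --seed 7 --out run/
edit-heritage call --reads run/fastq --targets run/ --out run/spectra.tsv
edit-heritage classify --spectra run/spectra.tsv --truth run/truth.tsv --out run/calls/
cat run/calls/recovery.json
```

Forward-simulate inheritance and summarise it:

```sh
edit-heritage inherit --parent-genotype "+1 bp(A)/-1 bp" --n 100 --seed 2 --out run/progeny.tsv
edit-heritage stats --cohort run/progeny.tsv --out run/stats.json
```

All commands accept `--seed` (every random draw flows from it through named
child streams, so outputs are byte-identical across runs) and an optional
YAML `--config` for designs, read parameters and classifier thresholds.

### Library use

```python
from edit_heritage import study_tables
from edit_heritage.segregation_stats import line_retention_reports

cohort = study_tables.t1_transmission("fuct1")
for report in line_retention_reports(cohort, "fuct1"):
    print(report.parent_id, report.parent_zygosity, report.retention)
```

## Testing

```sh
python -m pytest -q tests/
```

The suite (about 180 tests, ~90 s on one CPU) includes unit and property
tests per module plus `tests/test_acceptance.py`, which checks the study's
table arithmetic and the pipeline's property-based claims: score equivalence
with an independent hand-written Gotoh alignment oracle (1,000 seeded
trials), ≥ 99% per-class classifier recovery on 510 simulated plants at
2,000 reads / 0.1% error, 1:2:1 Mendelian recovery at n = 10,000, and
simulator conservation/determinism invariants.

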