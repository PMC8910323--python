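"""Target generation, read simulation and cohort construction."""

import numpy as np
import pytest

from edit_heritage.allele_model import REFERENCE_ALLELE, Genotype, parse_genotype_label
from edit_heritage.synthetic_data import (
    CHIMERA_SECTOR_HI,
    CHIMERA_SECTOR_LO,
    ReadSimParams,
    TruthPlant,
    generate_cohort,
    generate_target,
    read_fastq,
    simulate_reads,
    write_fastq,
)


class TestGenerateTarget:
    @pytest.mark.parametrize("gc, n_gc", [(0.30, 6), (0.60, 12), (0.0, 0), (1.0, 20)])
    def test_exact_protospacer_gc_count(self, gc, n_gc):
        site = generate_target(gc, seed=7)
        proto = site.reference[site.protospacer_start : site.protospacer_end]
        if site.strand == "plus":
            assert sum(b in "GC" for b in proto) == n_gc
        assert len(proto) == 20

    def test_minus_strand_gc_preserved_under_revcomp(self):
        site = generate_target(0.30, strand="minus", seed=7)
        proto = site.reference[site.protospacer_start : site.protospacer_end]
        # GC content is strand-symmetric
        assert sum(b in "GC" for b in proto) == 6

    def test_unrepresentable_gc_rejected(self):
        with pytest.raises(ValueError):
            generate_target(0.33)

    def test_too_short_amplicon_rejected(self):
        with pytest.raises(ValueError):
            generate_target(0.30, amplicon_length=50)

    def test_deterministic_per_seed(self):
        a = generate_target(0.60, strand="minus", seed=42)
        b = generate_target(0.60, strand="minus", seed=42)
        c = generate_target(0.60, strand="minus", seed=43)
        assert a == b
        assert a.reference != c.reference

    def test_cut_near_centre(self):
        site = generate_target(0.30, amplicon_length=300, seed=1)
        assert abs(site.cut_offset - 150) < 30


def _plant(label: str, plant_id: str = "p1") -> TruthPlant:
    return TruthPlant(plant_id, "T0", {"loc": parse_genotype_label(label)})


class TestSimulateReads:
    def test_read_count_and_length(self, plus_site):
        params = ReadSimParams(n_reads=50, error_rate=0.0, seed=3)
        reads = simulate_reads(_plant("-4 bp/-4 bp"), plus_site, params, locus="loc")
        assert len(reads) == 50
        assert all(len(r.sequence) == params.read_length for r in reads)

    def test_homozygous_is_degenerate_mixture(self, plus_site):
        params = ReadSimParams(n_reads=40, error_rate=0.0, seed=3)
        reads = simulate_reads(_plant("-4 bp/-4 bp"), plus_site, params, locus="loc")
        assert len({r.sequence for r in reads}) == 1

    def test_bi_allelic_split_within_binomial_bounds(self, plus_site):
        n = 4000
        params = ReadSimParams(n_reads=n, error_rate=0.0, seed=5)
        reads = simulate_reads(
            _plant("+1 bp(T)/-4 bp"), plus_site, params, locus="loc"
        )
        counts = {}
        for r in reads:
            counts[r.sequence] = counts.get(r.sequence, 0) + 1
        assert len(counts) == 2
        # 99.99% binomial bound: |k - n/2| < 4 * sqrt(n)/2
        k = max(counts.values())
        assert abs(k - n / 2) < 4 * np.sqrt(n) / 2

    def test_chimeric_fractions_recovered(self, plus_site):
        g = Genotype(
            tuple(
                parse_genotype_label("WT/+1 bp(T)/-4 bp/-7 bp").alleles
            ),
            (0.55, 0.10, 0.15, 0.20),
        )
        plant = TruthPlant("p1", "T0", {"loc": g})
        n = 8000
        params = ReadSimParams(n_reads=n, error_rate=0.0, seed=9)
        reads = simulate_reads(plant, plus_site, params, locus="loc")
        counts = {}
        for r in reads:
            counts[r.sequence] = counts.get(r.sequence, 0) + 1
        observed = sorted(c / n for c in counts.values())
        expected = sorted((0.55, 0.10, 0.15, 0.20))
        for obs, exp in zip(observed, expected):
            assert abs(obs - exp) < 4 * np.sqrt(exp * (1 - exp) / n)

    def test_deterministic_per_seed(self, plus_site):
        params = ReadSimParams(n_reads=30, error_rate=0.01, seed=11)
        a = simulate_reads(_plant("+1 bp(T)/-4 bp"), plus_site, params, locus="loc")
        b = simulate_reads(_plant("+1 bp(T)/-4 bp"), plus_site, params, locus="loc")
        assert a == b

    def test_error_rate_bounds_enforced(self):
        with pytest.raises(ValueError):
            ReadSimParams(error_rate=0.2)
        with pytest.raises(ValueError):
            ReadSimParams(read_length=10)

    def test_read_too_short_for_event_rejected(self, plus_site):
        params = ReadSimParams(n_reads=5, read_length=30, seed=0)
        with pytest.raises(ValueError):
            simulate_reads(_plant("-11 bp/-11 bp"), plus_site, params, locus="loc")

    def test_fastq_round_trip(self, plus_site, tmp_path):
        params = ReadSimParams(n_reads=10, error_rate=0.0, seed=2)
        reads = simulate_reads(_plant("WT"), plus_site, params, locus="loc")
        path = tmp_path / "x.fastq"
        write_fastq(reads, path)
        assert read_fastq(path) == reads


class TestGenerateCohort:
    def test_design_counts_respected(self, plus_site, minus_site):
        design = {
            "a": {"wild_type": 2, "homozygous": 3, "chimeric": 1},
            "b": {"bi_allelic": 4},
        }
        sites = {"a": plus_site, "b": minus_site}
        plants, reads, truth = generate_cohort(design, sites, seed=1)
        assert len(plants) == 6  # max over loci
        assert not reads  # no read params supplied
        a_rows = truth[truth["locus"] == "a"]
        assert dict(a_rows["zygosity"].value_counts()) == {
            "wild_type": 2,
            "homozygous": 3,
            "chimeric": 1,
        }
        b_rows = truth[truth["locus"] == "b"]
        # padded to cohort size with wild type
        assert dict(b_rows["zygosity"].value_counts()) == {
            "bi_allelic": 4,
            "wild_type": 2,
        }

    def test_chimera_sector_fractions_in_band(self, plus_site):
        plants, _, _ = generate_cohort(
            {"a": {"chimeric": 20}}, {"a": plus_site}, seed=3
        )
        for plant in plants:
            g = plant.genotypes["a"]
            assert g.is_chimeric
            fracs = g.normalized_fractions()
            for allele, frac in zip(g.alleles, fracs):
                if allele.is_mutant:
                    assert CHIMERA_SECTOR_LO - 1e-9 <= frac <= CHIMERA_SECTOR_HI + 1e-9

    def test_reads_deterministic_per_seed(self, plus_site):
        design = {"a": {"bi_allelic": 2}}
        params = ReadSimParams(n_reads=20, seed=0)
        _, r1, _ = generate_cohort(design, {"a": plus_site}, seed=5, read_params=params)
        _, r2, _ = generate_cohort(design, {"a": plus_site}, seed=5, read_params=params)
        assert r1 == r2

    def test_empty_design_rejected(self, plus_site):
        with pytest.raises(ValueError):
            generate_cohort({}, {"a": plus_site})
        with pytest.raises(ValueError):
            generate_cohort({"a": {}}, {"a": plus_site})

    def test_unknown_class_rejected(self, plus_site):
        with pytest.raises(ValueError):
            generate_cohort({"a": {"triploid": 1}}, {"a": plus_site})

    def test_missing_site_rejected(self, plus_site):
        with pytest.raises(ValueError):
            generate_cohort({"b": {"wild_type": 1}}, {"a": plus_site})


def test_t0_plant_cannot_have_parent():
    with pytest.raises(ValueError):
        TruthPlant("x", "T0", {"loc": Genotype((REFERENCE_ALLELE, REFERENCE_ALLELE))},
                   parent_id="y")
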