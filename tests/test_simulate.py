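"""Synthetic genome and read simulation: composition, mutation and determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repeatscape._align import hamming, revcomp
from repeatscape.simulate import (
    GenomeSpec,
    LTRFamilySpec,
    TandemFamilySpec,
    build_genome,
    default_olive_spec,
    mutate,
    random_unit,
    simulate_reads,
)

EXPECTED_UNITS = {"Oe80": 80, "Oe178": 178, "Oe86": 86, "Oe179": 179, "Oe218": 218, "Oe51": 51}
EXPECTED_GC = {"Oe80": 0.454, "Oe178": 0.432, "Oe86": 0.360, "Oe179": 0.360,
               "Oe218": 0.418, "Oe51": 0.335}


class TestDefaultSpec:
    def test_six_families_with_published_units_and_gc(self):
        spec = default_olive_spec()
        fams = {f.name: f for f in spec.tandem_families}
        assert {f: fams[f].unit_length for f in fams} == EXPECTED_UNITS
        for name, gc in EXPECTED_GC.items():
            assert fams[name].gc == pytest.approx(gc)

    def test_tandem_fraction_near_a_third_of_genome(self):
        spec = default_olive_spec(2_000_000)
        tandem = sum(f.nominal_length for f in spec.tandem_families)
        assert 0.29 <= tandem / spec.nominal_genome_length <= 0.33

    def test_ltr_fraction_near_published_superfamily_percents(self):
        spec = default_olive_spec(2_000_000)
        ltr = sum(f.nominal_length for f in spec.ltr_families)
        assert 0.36 <= ltr / spec.nominal_genome_length <= 0.42

    def test_copy_numbers_scale_linearly_with_genome_size(self):
        big = {f.name: f.copy_number for f in default_olive_spec(2_000_000).tandem_families}
        small = {f.name: f.copy_number for f in default_olive_spec(1_000_000).tandem_families}
        for name in big:
            assert small[name] == pytest.approx(big[name] / 2, abs=1)


class TestBuildGenome:
    def test_zero_rate_copies_identical_to_unit(self, make_dna):
        unit = make_dna(60)
        fam = TandemFamilySpec(name="f", copy_number=100, unit_sequence=unit,
                               per_copy_substitution_rate=0.0, n_arrays=2)
        spec = GenomeSpec(tandem_families=[fam], background_length=5000, seed=3)
        genome, truth = build_genome(spec)
        tandem_ivs = [iv for iv in truth.intervals if iv.category == "tandem"]
        assert len(tandem_ivs) == 100
        for iv in tandem_ivs:
            assert genome[iv.start : iv.end] == unit

    def test_intact_elements_yield_two_ltr_and_one_internal_interval(self):
        fam = LTRFamilySpec(name="g", superfamily="Gypsy", ltr_length=150,
                            internal_length=800, n_intact=5)
        spec = GenomeSpec(ltr_families=[fam], background_length=8000, seed=4)
        _, truth = build_genome(spec)
        cats = [iv.category for iv in truth.intervals]
        assert cats.count("ltr") == 10
        assert cats.count("internal") == 5

    def test_mean_hamming_distance_matches_binomial_expectation(self, make_dna):
        unit = make_dna(178)
        fam = TandemFamilySpec(name="f", copy_number=200, unit_sequence=unit,
                               per_copy_substitution_rate=0.02, n_arrays=1)
        spec = GenomeSpec(tandem_families=[fam], background_length=2000, seed=5)
        genome, truth = build_genome(spec)
        dists = [
            hamming(genome[iv.start : iv.end], unit)
            for iv in truth.intervals
            if iv.category == "tandem"
        ]
        # binomial expectation 178 * 0.02 = 3.56, sd of the mean ~ 0.13
        assert np.mean(dists) == pytest.approx(3.56, abs=0.6)

    def test_byte_identical_for_fixed_seed(self):
        spec1 = default_olive_spec(60_000, seed=9)
        spec2 = default_olive_spec(60_000, seed=9)
        g1, t1 = build_genome(spec1)
        g2, t2 = build_genome(spec2)
        assert g1 == g2
        assert t1.intervals == t2.intervals

    def test_interval_lengths_plus_background_equal_genome_length(self):
        spec = default_olive_spec(80_000, seed=2)
        genome, truth = build_genome(spec)
        placed = sum(iv.end - iv.start for iv in truth.intervals)
        assert placed + spec.background_length == len(genome)

    def test_genome_gc_close_to_length_weighted_mixture(self):
        spec = default_olive_spec(100_000, seed=6)
        genome, truth = build_genome(spec)
        from repeatscape.tandem import gc_content

        mix = 0.0
        for fam in spec.tandem_families:
            mix += fam.gc * fam.nominal_length
        for fam in spec.ltr_families:
            mix += fam.gc * fam.nominal_length
        mix += spec.background_gc * spec.background_length
        mix /= spec.nominal_genome_length
        assert gc_content(genome) == pytest.approx(mix, abs=0.02)

    def test_oversized_families_raise_sizing_error(self, make_dna):
        fam = TandemFamilySpec(name="f", copy_number=100, unit_sequence=make_dna(50))
        with pytest.raises(ValueError, match="background"):
            build_genome(GenomeSpec(tandem_families=[fam], background_length=3))


class TestRandomUnit:
    @pytest.mark.parametrize("gc", [0.335, 0.418, 0.454])
    def test_hits_target_gc_within_tolerance(self, gc, rng):
        from repeatscape.tandem import gc_content

        unit = random_unit(80, gc, rng)
        assert gc_content(unit) == pytest.approx(gc, abs=0.02)

    def test_mutate_rate_zero_is_identity(self, make_dna):
        seq = make_dna(300)
        assert mutate(seq, 0.0, np.random.default_rng(0)) == seq


class TestSimulateReads:
    def test_read_count_formula(self, make_dna):
        genome = make_dna(10_000)
        reads = simulate_reads(genome, 8.1, 75, seed=1)
        assert len(reads) == 1080  # round(8.1 * 10000 / 75)

    def test_error_free_reads_are_genome_substrings(self, make_dna):
        genome = make_dna(2_000)
        reads = simulate_reads(genome, 2.0, 75, substitution_error_rate=0.0, seed=2)
        for seq, (start, strand) in zip(reads.sequences[:20], reads.origins[:20]):
            window = genome[int(start) : int(start) + 75]
            assert seq == (window if strand == 0 else revcomp(window))

    def test_zero_coverage_rejected(self, make_dna):
        with pytest.raises(ValueError):
            simulate_reads(make_dna(1000), 0.0, 75)

    def test_depth_poisson_like(self, make_dna):
        genome = make_dna(10_000)
        reads = simulate_reads(genome, 8.1, 75, substitution_error_rate=0.005, seed=3)
        depth = np.zeros(len(genome) + 1)
        for start, _ in reads.origins:
            depth[int(start)] += 1
            depth[int(start) + 75] -= 1
        depth = np.cumsum(depth[:-1])[74:-74]  # interior positions
        assert depth.mean() == pytest.approx(8.1, rel=0.05)
        assert depth.var() == pytest.approx(8.1, rel=0.30)

    def test_byte_identical_reads_for_fixed_seed(self, make_dna):
        genome = make_dna(3_000)
        r1 = simulate_reads(genome, 3.0, 75, 0.01, seed=7)
        r2 = simulate_reads(genome, 3.0, 75, 0.01, seed=7)
        assert r1.sequences == r2.sequences


@given(st.text(alphabet="ACGT", min_size=1, max_size=200))
@settings(max_examples=50, derandomize=True)
def test_revcomp_is_an_involution(seq):
    assert revcomp(revcomp(seq)) == seq
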