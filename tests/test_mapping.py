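"""Read mapper: placement rules, multiread randomness, calibration, oracle."""

import numpy as np
import pytest
from scipy import stats

from repeatscape._align import revcomp
from repeatscape.mapping import (
    MappingParams,
    calibrate_mapping,
    map_reads,
)
from repeatscape.simulate import mutate, simulate_reads


def brute_force_best_contigs(read: str, contigs: dict[str, str]) -> tuple[float, set]:
    """Exhaustive ungapped scan of every placement of the read (both strands)
    on every contig; returns (best identity, set of contigs achieving it)."""
    best_ident, best = -1.0, set()
    for cid, seq in contigs.items():
        for oriented in (read, revcomp(read)):
            L = len(oriented)
            for off in range(0, len(seq) - L + 1):
                m = sum(a == b for a, b in zip(oriented, seq[off : off + L]))
                ident = m / L
                if ident > best_ident:
                    best_ident, best = ident, {cid}
                elif ident == best_ident:
                    best.add(cid)
    return best_ident, best


class TestMapReads:
    def test_unique_substring_maps_with_full_bases(self, make_dna):
        contig = make_dna(400)
        res = map_reads([contig[100:175]], {"c": contig}, MappingParams(seed=1))
        assert res.assignments == ["c"]
        assert res.mapped_bases["c"] == 75

    def test_reverse_complement_read_maps(self, make_dna):
        contig = make_dna(400)
        res = map_reads([revcomp(contig[50:125])], {"c": contig}, MappingParams(seed=1))
        assert res.assignments == ["c"]

    def test_low_identity_read_rejected(self, make_dna):
        contig = make_dna(400)
        read = mutate(contig[100:175], 0.4, np.random.default_rng(0))
        # ~30 mismatches out of 75: identity ~0.6 < similarity 0.8
        res = map_reads([read], {"c": contig}, MappingParams(similarity=0.8, seed=1))
        assert res.assignments == [None]

    def test_multiread_split_is_binomial_fair(self, make_dna):
        shared = make_dna(150)
        contigs = {"X": make_dna(30) + shared, "Y": shared + make_dna(30)}
        reads = [shared[20:95]] * 10_000
        res = map_reads(reads, contigs, MappingParams(seed=42))
        n_x = res.n_mapped_reads["X"]
        assert res.n_matched == 10_000
        p = stats.binomtest(n_x, 10_000, 0.5).pvalue
        assert p > 0.001

    def test_read_conservation_across_parameter_sets(self, make_dna):
        genome = make_dna(3_000)
        reads = simulate_reads(genome, 3.0, 75, 0.01, seed=2)
        contigs = {"a": genome[:1500], "b": genome[1500:]}
        for sim in (0.8, 0.9, 0.95):
            res = map_reads(reads, contigs, MappingParams(similarity=sim, seed=3))
            assert res.n_matched + res.n_unmatched == len(reads)

    def test_raising_similarity_never_increases_matches(self, make_dna):
        genome = make_dna(3_000)
        reads = simulate_reads(genome, 3.0, 75, 0.03, seed=4)
        contigs = {"a": genome}
        matched = [
            map_reads(reads, contigs, MappingParams(similarity=s, seed=5)).n_matched
            for s in (0.8, 0.9, 0.95, 1.0)
        ]
        assert matched == sorted(matched, reverse=True)

    def test_matches_brute_force_oracle(self, make_dna):
        rng = np.random.default_rng(77)
        contigs = {f"c{i}": make_dna(300) for i in range(5)}
        reads = []
        for i in range(50):
            cid = f"c{i % 5}"
            start = int(rng.integers(0, 225))
            read = contigs[cid][start : start + 75]
            read = mutate(read, 0.02, rng)
            if rng.random() < 0.5:
                read = revcomp(read)
            reads.append(read)
        params = MappingParams(similarity=0.8, length_fraction=1.0, seed=6)
        res = map_reads(reads, contigs, params)
        for read, assigned in zip(reads, res.assignments):
            ident, best = brute_force_best_contigs(read, contigs)
            if assigned is None:
                assert ident < params.similarity
            else:
                assert assigned in best

    def test_total_mapped_bases_track_coverage(self, make_dna):
        genome = make_dna(5_000)
        reads = simulate_reads(genome, 6.0, 75, 0.0, seed=8)
        res = map_reads(reads, {"g": genome}, MappingParams(length_fraction=0.5, seed=9))
        total = res.mapped_bases["g"]
        assert total == pytest.approx(6.0 * len(genome), rel=0.05)

    def test_empty_contig_set_leaves_reads_unmapped(self, make_dna):
        res = map_reads([make_dna(75)], {}, MappingParams(seed=1))
        assert res.assignments == [None]
        assert res.n_unmatched == 1


class TestAverageCoverage:
    def test_two_half_length_reads_give_unit_coverage(self, make_dna):
        contig = make_dna(100)
        res = map_reads([contig[:50], contig[50:]], {"c": contig},
                        MappingParams(length_fraction=0.5, seed=1))
        assert res.average_coverage("c") == pytest.approx(1.0)

    def test_no_reads_give_zero(self, make_dna):
        res = map_reads([], {"c": make_dna(100)}, MappingParams(seed=1))
        assert res.average_coverage("c") == 0.0

    def test_unknown_contig_raises(self, make_dna):
        res = map_reads([], {"c": make_dna(100)}, MappingParams(seed=1))
        with pytest.raises(KeyError):
            res.average_coverage("zzz")


class TestCalibration:
    def _references(self, make_dna, copies=(1, 5, 20, 100)):
        refs, counts = {}, {}
        for i, c in enumerate(copies):
            refs[f"ref{i}"] = make_dna(300)
            counts[f"ref{i}"] = float(c)
        return refs, counts

    def _reads_for(self, refs, counts, rng, error=0.0):
        reads = []
        for rid, seq in refs.items():
            for _ in range(int(counts[rid]) * 4):
                start = int(rng.integers(0, len(seq) - 75))
                reads.append(mutate(seq[start : start + 75], error, rng))
        return reads

    def test_proportional_coverage_yields_perfect_correlation(self, make_dna, rng):
        refs, counts = self._references(make_dna)
        reads = self._reads_for(refs, counts, rng)
        grid = [MappingParams(similarity=s, seed=3) for s in (0.8, 0.95)]
        result = calibrate_mapping(reads, refs, counts, grid)
        assert result.table["pearson_r"].max() > 0.99
        assert result.stable

    def test_shuffled_copy_numbers_flagged_unstable(self, make_dna, rng):
        refs, counts = self._references(make_dna)
        reads = self._reads_for(refs, counts, rng)
        shuffled = dict(zip(counts, [20.0, 100.0, 1.0, 5.0]))
        grid = [MappingParams(similarity=s, seed=3) for s in (0.8, 0.95)]
        result = calibrate_mapping(reads, refs, shuffled, grid)
        assert abs(result.table["pearson_r"]).max() < 0.9
        assert not result.stable

    def test_selected_similarity_tolerates_the_read_error_rate(self, make_dna, rng):
        refs, counts = self._references(make_dna)
        reads = self._reads_for(refs, counts, rng, error=0.05)
        grid = [MappingParams(similarity=s, seed=3) for s in (0.8, 0.99)]
        result = calibrate_mapping(reads, refs, counts, grid)
        assert result.best_params.similarity <= 1 - 0.05 + 0.05  # 0.8 grid point wins
        assert result.best_params.similarity == 0.8

    def test_too_few_references_rejected(self, make_dna):
        with pytest.raises(ValueError, match="at least 3"):
            calibrate_mapping([], {"a": make_dna(100), "b": make_dna(100)},
                              {"a": 1.0, "b": 2.0})

    def test_zero_variance_copy_numbers_rejected(self, make_dna):
        refs = {f"r{i}": make_dna(100) for i in range(3)}
        with pytest.raises(ValueError, match="variance"):
            calibrate_mapping([], refs, {r: 5.0 for r in refs})
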