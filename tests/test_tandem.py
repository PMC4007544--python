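"""Satellite analysis: period, consensus, monomers, pi, GC, NJ tree."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix

from repeatscape.simulate import mutate, simulate_reads
from repeatscape.tandem import (
    build_consensus,
    detect_period,
    extract_units,
    gc_content,
    nj_tree,
    nucleotide_diversity,
    pairwise_pdistance,
    star_align,
)


class TestGC:
    @pytest.mark.parametrize("seq,expected", [("ATGC", 0.5), ("AAAA", 0.0), ("GCGC", 1.0)])
    def test_known_values(self, seq, expected):
        assert gc_content(seq) == expected

    def test_ambiguity_codes_excluded(self):
        assert gc_content("ATGCNNNN") == 0.5

    def test_no_unambiguous_bases_rejected(self):
        with pytest.raises(ValueError):
            gc_content("NNN")


class TestDetectPeriod:
    def test_pure_four_mer_repeat(self):
        assert detect_period("ACGT" * 50) == 4

    def test_noisy_51_nt_unit(self, make_dna):
        rng = np.random.default_rng(8)
        unit = make_dna(51)
        array = "".join(mutate(unit, 0.02, rng) for _ in range(20))
        assert detect_period(array) == 51

    def test_random_sequence_has_no_period(self, make_dna):
        false_positives = sum(
            detect_period(make_dna(200)) is not None for _ in range(100)
        )
        assert false_positives <= 2

    def test_multiple_of_true_period_not_returned(self, make_dna):
        unit = make_dna(23)
        for k in (3, 5, 10):
            p = detect_period(unit * k)
            assert p is not None and unit[:p] * (23 // p) and 23 % p == 0


class TestConsensus:
    def test_identical_units_return_the_unit(self):
        assert build_consensus(["ACGTAC"] * 3) == "ACGTAC"

    def test_majority_wins_per_column(self):
        assert build_consensus(["ACGT", "ACGT", "ACTT"]) == "ACGT"

    def test_recovers_true_unit_from_diverged_copies(self, make_dna):
        rng = np.random.default_rng(4)
        unit = make_dna(178)
        copies = [mutate(unit, 0.02, rng) for _ in range(100)]
        consensus = build_consensus(copies, unit[: len(unit)])
        diffs = sum(a != b for a, b in zip(consensus, unit))
        assert len(consensus) == len(unit)
        assert diffs <= 2

    def test_single_unit_rejected(self):
        with pytest.raises(ValueError):
            build_consensus(["ACGT"])


class TestExtractUnits:
    def test_exact_consensus_in_read_is_extracted(self, make_dna):
        consensus = make_dna(80)
        read = make_dna(60) + consensus + make_dna(60)
        units = extract_units([("r1", read)], consensus)
        assert units == [("r1", consensus)]

    def test_best_of_two_copies_per_read(self, make_dna):
        rng = np.random.default_rng(5)
        consensus = make_dna(80)
        good = mutate(consensus, 0.01, rng)
        bad = mutate(consensus, 0.08, rng)
        read = make_dna(30) + good + make_dna(30) + bad + make_dna(30)
        units = extract_units([("r1", read)], consensus)
        assert len(units) == 1
        assert units[0][1] == good

    def test_units_come_from_distinct_reads(self, make_dna):
        rng = np.random.default_rng(6)
        unit = make_dna(80)
        genome = "".join(mutate(unit, 0.02, rng) for _ in range(120)) + make_dna(3000)
        reads = simulate_reads(genome, 16.0, 400, 0.005, seed=7)  # ~500 reads
        units = extract_units(reads, unit, n=100)
        assert len(units) == 100
        assert len({rid for rid, _ in units}) == 100


class TestNucleotideDiversity:
    def test_identical_pair_gives_zero(self):
        assert nucleotide_diversity(["ACGTACGTAC"] * 2)[0] == 0.0

    def test_one_difference_over_ten_sites(self):
        pi, _ = nucleotide_diversity(["ACGTACGTAC", "ACGTACGTAT"])
        assert pi == pytest.approx(0.1)

    def test_matches_brute_force_double_loop(self, make_dna):
        seqs = [make_dna(20) for _ in range(5)]
        pi, _ = nucleotide_diversity(seqs)
        n = len(seqs)
        total = sum(
            sum(a != b for a, b in zip(seqs[i], seqs[j])) / 20
            for i, j in itertools.combinations(range(n), 2)
        )
        assert pi == pytest.approx(2 * total / (n * (n - 1)))

    def test_invariant_under_reordering(self, make_dna):
        rng = np.random.default_rng(10)
        seqs = [make_dna(30) for _ in range(8)]
        pi1, sd1 = nucleotide_diversity(seqs)
        order = rng.permutation(8)
        pi2, sd2 = nucleotide_diversity([seqs[i] for i in order])
        assert pi1 == pytest.approx(pi2)
        assert sd1 == pytest.approx(sd2)

    def test_pairwise_deletion_skips_gapped_sites(self):
        pi, _ = nucleotide_diversity(["ACGT-CGTAC", "ACGTACGTAT"])
        # 9 comparable sites, 1 difference
        assert pi == pytest.approx(1 / 9)

    def test_ranks_with_simulated_divergence(self, make_dna):
        rng = np.random.default_rng(11)
        base = make_dna(150)
        pis = []
        for rate in (0.01, 0.03, 0.06):
            copies = [mutate(base, rate, rng) for _ in range(40)]
            pis.append(nucleotide_diversity(star_align(copies, base))[0])
        assert pis == sorted(pis)

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            nucleotide_diversity(["ACGT"])


class TestNJTree:
    def test_three_taxa_closed_form_branch_lengths(self):
        dm = DistanceMatrix([[0, 4, 6], [4, 0, 8], [6, 8, 0]], ["a", "b", "c"])
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        # v_a = (d_ab + d_ac - d_bc)/2 etc.
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(3.0)
        assert lengths["c"] == pytest.approx(5.0)

    def test_four_taxon_additive_tree_recovered(self):
        # tree ((a:1,b:2):1,(c:1.5,d:2.5)) -> additive distances
        d = {
            ("a", "b"): 3.0, ("a", "c"): 3.5, ("a", "d"): 4.5,
            ("b", "c"): 4.5, ("b", "d"): 5.5, ("c", "d"): 4.0,
        }
        ids = ["a", "b", "c", "d"]
        mat = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = ids.index(x), ids.index(y)
            mat[i, j] = mat[j, i] = v
        tree = nj_tree(DistanceMatrix(mat, ids))
        # the split ab|cd must be present
        for node in tree.non_tips():
            clade = {t.name for t in node.tips()}
            assert clade in ({"a", "b"}, {"c", "d"}, {"a", "b", "c", "d"}) or \
                set(ids) - clade in ({"a", "b"}, {"c", "d"})
        tip_dist = tree.tip_tip_distances(ids)
        for (x, y), v in d.items():
            assert tip_dist[x, y] == pytest.approx(v)

    def test_two_simulated_families_form_separate_clades(self, make_dna):
        rng = np.random.default_rng(13)
        fam_a, fam_b = make_dna(100), make_dna(100)
        seqs, ids = [], []
        for tag, base in (("A", fam_a), ("B", fam_b)):
            for i in range(6):
                seqs.append(mutate(base, 0.03, rng))
                ids.append(f"{tag}{i}")
        msa = star_align(seqs, seqs[0])
        tree = nj_tree(pairwise_pdistance(msa, ids))
        clades = [frozenset(t.name for t in n.tips()) for n in tree.non_tips()]
        a_set = frozenset(i for i in ids if i.startswith("A"))
        b_set = frozenset(i for i in ids if i.startswith("B"))
        all_ids = frozenset(ids)
        assert any(c in (a_set, all_ids - a_set, b_set, all_ids - b_set) for c in clades)

    def test_bootstrap_supports_strong_split(self, make_dna):
        rng = np.random.default_rng(14)
        fam_a, fam_b = make_dna(120), make_dna(120)
        seqs, ids = [], []
        for tag, base in (("A", fam_a), ("B", fam_b)):
            for i in range(4):
                seqs.append(mutate(base, 0.02, rng))
                ids.append(f"{tag}{i}")
        msa = star_align(seqs, seqs[0])
        dm = pairwise_pdistance(msa, ids)
        tree = nj_tree(dm, alignment=msa, bootstrap=50, seed=3)
        supports = [float(n.name) for n in tree.non_tips() if n.name]
        assert supports and max(supports) > 0.9

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix([[0, 1], [1, 0]], ["a", "b"]))
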