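"""Tiling, thermodynamics, screens (vs exhaustive oracles) and full design runs."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from longcap.genome_io import TargetRegion
from longcap.primer_design import (
    DesignParams,
    KmerIndex,
    cross_dimer_score,
    design_primer_set,
    gc_content,
    hairpin_screen,
    melting_temperature,
    mutual_three_prime_overlap,
    tile_region,
    uniqueness_screen,
)
from longcap.util import revcomp

from conftest import random_sequence

dna = st.text(alphabet="ACGT", min_size=1, max_size=25)
dna20 = st.text(alphabet="ACGT", min_size=20, max_size=20)


# ---------------------------------------------------------------- tiling


class TestTileRegion:
    def test_region_equal_to_spacing_is_one_tile(self):
        assert tile_region(8000, 8000) == [(0, 8000)]

    def test_four_mbp_at_8kbp_gives_500_tiles(self):
        assert len(tile_region(4_000_002, 8000)) == 500

    def test_balanced_partition(self):
        tiles = tile_region(25_000, 8000)
        lengths = sorted(e - s for s, e in tiles)
        assert lengths == [8333, 8333, 8334]

    @given(st.integers(1, 500_000), st.integers(1, 20_000))
    def test_tiles_partition_the_region(self, length, spacing):
        tiles = tile_region(length, spacing)
        assert tiles[0][0] == 0 and tiles[-1][1] == length
        for (s1, e1), (s2, e2) in zip(tiles, tiles[1:]):
            assert e1 == s2
        sizes = {e - s for s, e in tiles}
        assert max(sizes) - min(sizes) <= 1
        assert len(tiles) == max(1, int(length / spacing + 0.5))

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            tile_region(0, 10)
        with pytest.raises(ValueError):
            tile_region(100, 0)


# ---------------------------------------------------------------- gc / tm


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATAT", 0.0), ("GCGC", 1.0), ("ACGTACGTAC", 0.5)],
    )
    def test_known_values(self, seq, expected):
        assert gc_content(seq) == expected

    def test_ambiguous_rejected(self):
        with pytest.raises(ValueError):
            gc_content("ACGN")


class TestMeltingTemperature:
    def test_gc_rich_melts_higher_than_at_rich(self):
        assert melting_temperature("GCGCGCGCGCGCGCGCGCGC") > melting_temperature(
            "ATATATATATATATATATAT"
        )

    def test_hand_computed_nn_sum(self):
        # AGCTTGCAACGGTCATAGGC: 19 steps summed from the unified table by hand
        # gives dH = -157.7 kcal/mol, dS = -423.1 cal/mol/K (incl. terminal
        # A/T +2.3/+4.1 and G/C +0.1/-2.8 initiations); with the entropic
        # salt term at 50 mM and C/4 at 0.25 uM the predicted Tm is 57.45 C.
        from longcap.thermo import duplex_dh_ds

        dh, ds = duplex_dh_ds("AGCTTGCAACGGTCATAGGC")
        assert dh == pytest.approx(-157.7, abs=1e-9)
        assert ds == pytest.approx(-423.1, abs=1e-9)
        assert melting_temperature("AGCTTGCAACGGTCATAGGC") == pytest.approx(
            57.45, abs=0.1
        )

    @given(dna20)
    def test_reverse_complement_invariance(self, seq):
        assert melting_temperature(seq) == pytest.approx(
            melting_temperature(revcomp(seq)), abs=1e-9
        )

    @given(st.text(alphabet="ACGT", min_size=8, max_size=40))
    def test_matches_independent_nn_implementation(self, seq):
        """Cross-check against Biopython's SantaLucia-1998 NN model."""
        from Bio.SeqUtils import MeltingTemp as mt

        expected = mt.Tm_NN(
            seq, nn_table=mt.DNA_NN3, Na=50, dnac1=125, dnac2=125, saltcorr=5
        )
        assert melting_temperature(seq) == pytest.approx(expected, abs=1e-6)

    def test_length_bounds(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGT")


# ---------------------------------------------------------------- uniqueness


def _occ(text, pattern):
    return sum(
        1 for i in range(len(text) - len(pattern) + 1) if text[i : i + len(pattern)] == pattern
    )


def _uniqueness_oracle(cand, background, k):
    """Both-strand k-mer counts via the reverse-complemented background."""
    rbg = revcomp(background)
    rcand = revcomp(cand)
    best = 0
    for i in range(len(cand) - k + 1):
        km = cand[i : i + k]
        total = _occ(background, km) + _occ(rbg, km) - _occ(cand, km) - _occ(rcand, km)
        best = max(best, max(total, 0))
    return best


class TestUniquenessScreen:
    def test_unique_candidate_scores_zero(self, rng):
        bg = random_sequence(rng, 4000)
        cand = bg[1000:1020]
        result = uniqueness_screen(cand, bg, k=16, max_kmer_hits=1)
        assert result.score == 0 and result.passed

    def test_tandem_duplication_fails_strict_threshold(self, rng):
        unit = random_sequence(rng, 500)
        bg = random_sequence(rng, 1000) + unit + unit + random_sequence(rng, 1000)
        cand = unit[100:120]
        strict = uniqueness_screen(cand, bg, k=16, max_kmer_hits=0)
        lenient = uniqueness_screen(cand, bg, k=16, max_kmer_hits=1)
        assert strict.score >= 1 and not strict.passed
        assert lenient.passed

    def test_reverse_complement_occurrence_counts(self, rng):
        cand = random_sequence(rng, 20)
        bg = random_sequence(rng, 500) + cand + random_sequence(rng, 500) + revcomp(cand)
        result = uniqueness_screen(cand, bg, k=16, max_kmer_hits=0)
        assert result.score >= 1

    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        bg = random_sequence(rng, 300)
        start = data.draw(st.integers(0, 280))
        cand = bg[start : start + 20]
        k = data.draw(st.integers(8, 16))
        result = uniqueness_screen(cand, bg, k=k, max_kmer_hits=1)
        assert result.score == _uniqueness_oracle(cand, bg, k)

    def test_background_shorter_than_k(self):
        with pytest.raises(ValueError):
            uniqueness_screen("ACGTACGTACGTACGTAC", "ACGT", k=16)

    def test_kmer_index_counts_match_string_count(self, rng):
        bg = random_sequence(rng, 2000)
        idx = KmerIndex(bg, 10)
        for start in (0, 500, 1990):
            km = bg[start : start + 10]
            assert idx.count(km) == _occ(bg, km)


# ---------------------------------------------------------------- hairpin


def _hairpin_oracle(seq, min_loop):
    """Exhaustive search over all (upstream, downstream) substring pairs."""
    n = len(seq)
    best = 0
    for s in range(1, n // 2 + 1):
        for i in range(n - s + 1):
            for j in range(i + s + min_loop, n - s + 1):
                if seq[i : i + s] == revcomp(seq[j : j + s]):
                    best = max(best, s)
    return best


class TestHairpinScreen:
    def test_homopolymer_has_no_stem(self):
        result = hairpin_screen("A" * 20, min_stem=4, min_loop=3)
        assert result.stem == 0 and result.passed

    def test_perfect_four_stem(self):
        result = hairpin_screen("GGGGAAAACCCC", min_stem=4, min_loop=3)
        assert result.stem == 4 and not result.passed
        p, q = result.coords
        assert (p, q) == (0, 11)

    @given(dna, st.integers(0, 4))
    def test_matches_exhaustive_oracle(self, seq, min_loop):
        result = hairpin_screen(seq, min_stem=4, min_loop=min_loop)
        assert result.stem == _hairpin_oracle(seq, min_loop)


# ---------------------------------------------------------------- dimers


def _dimer_oracle(a, b):
    """Longest common substring of a and revcomp(b), plus the 3'-anchored
    variant as the longest suffix of a (or prefix of revcomp(b)) occurring
    in the other sequence."""
    rb = revcomp(b)
    best = 0
    for length in range(1, min(len(a), len(rb)) + 1):
        subs = {a[i : i + length] for i in range(len(a) - length + 1)}
        if any(rb[j : j + length] in subs for j in range(len(rb) - length + 1)):
            best = length
    best3 = 0
    for length in range(1, len(a) + 1):
        if a[-length:] in rb:
            best3 = length
    for length in range(1, len(rb) + 1):
        if rb[:length] in a:
            best3 = max(best3, length)
    return best, best3


class TestCrossDimer:
    def test_full_complement(self):
        assert cross_dimer_score("AAAA", "TTTT") == (4, 4)

    def test_palindrome_self_dimer(self):
        assert cross_dimer_score("ACGT", "ACGT") == (4, 4)

    @given(dna, dna)
    def test_matches_exhaustive_oracle(self, a, b):
        score = cross_dimer_score(a, b)
        assert tuple(score) == _dimer_oracle(a, b)

    @given(dna, dna)
    def test_symmetric_in_arguments(self, a, b):
        assert cross_dimer_score(a, b) == cross_dimer_score(b, a)

    @given(dna, dna)
    def test_mutual_three_prime_overlap_symmetric_and_bounded(self, a, b):
        r = mutual_three_prime_overlap(a, b)
        assert r == mutual_three_prime_overlap(b, a)
        assert 0 <= r <= min(len(a), len(b))
        if r:
            assert a[-r:] == revcomp(b)[:r]
        # a mutual-3' duplex is in particular a 3'-anchored run
        assert r <= cross_dimer_score(a, b).max_3prime_run


# ---------------------------------------------------------------- design


class TestDesignPrimerSet:
    def test_deterministic(self, small_region):
        a = design_primer_set(small_region)
        b = design_primer_set(small_region, seed=123)
        assert a.primers == b.primers
        assert a.unfilled_tiles == b.unfilled_tiles

    def test_every_primer_satisfies_every_constraint(self, small_region):
        params = DesignParams()
        pset = design_primer_set(small_region, params)
        assert pset.primers
        blocked = small_region.local_mask()
        for p in pset.primers:
            assert params.primer_len_min <= len(p) <= params.primer_len_max
            assert p.sequence == small_region.sequence[p.start : p.end]
            assert params.gc_min <= p.gc_fraction <= params.gc_max
            assert p.gc_fraction == pytest.approx(gc_content(p.sequence))
            assert abs(p.tm_C - params.tm_target_C) <= params.tm_tolerance_C
            assert p.tm_C == pytest.approx(melting_temperature(p.sequence))
            assert not blocked[p.start : p.end].any()
            hp = hairpin_screen(
                p.sequence, params.max_hairpin_stem, params.min_hairpin_loop
            )
            assert hp.passed
            uq = uniqueness_screen(
                p.sequence,
                small_region.sequence,
                k=params.uniqueness_k,
                max_kmer_hits=params.max_kmer_hits,
            )
            assert uq.passed and p.uniqueness_score == uq.score

    def test_emitted_set_is_mutually_dimer_compatible(self, small_region):
        params = DesignParams()
        pset = design_primer_set(small_region, params)
        primers = pset.primers
        for i, a in enumerate(primers):
            for b in primers[i:]:
                assert cross_dimer_score(a.sequence, b.sequence).max_run <= (
                    params.max_dimer_run
                )
                assert (
                    mutual_three_prime_overlap(a.sequence, b.sequence)
                    <= params.max_3prime_dimer_run
                )

    def test_one_primer_per_tile_near_center(self, small_region):
        pset = design_primer_set(small_region)
        assert len(pset.primers) + len(pset.unfilled_tiles) == len(pset.tiles)
        filled = [i for i in range(len(pset.tiles)) if i not in pset.unfilled_tiles]
        for idx, p in zip(filled, pset.primers):
            t0, t1 = pset.tiles[idx]
            assert t0 <= p.start and p.end <= t1

    def test_adjacent_primer_spacing(self, small_region):
        params = DesignParams()
        pset = design_primer_set(small_region, params)
        tile_len = max(e - s for s, e in pset.tiles)
        centers = [(p.start + p.end) / 2 for p in pset.primers]
        for c1, c2 in zip(centers, centers[1:]):
            assert abs((c2 - c1) - params.spacing_bp) <= tile_len

    def test_fully_masked_tile_is_unfilled(self, rng):
        n = 24_000
        region = TargetRegion(
            "reg", "reg", 0, n, random_sequence(rng, n), repeat_mask=[(8000, 16000)]
        )
        pset = design_primer_set(region)
        assert 1 in pset.unfilled_tiles
        assert len(pset.primers) == 2

    def test_dense_spacing_warns_on_low_coverage_ratio(self, rng):
        n = 50_000
        region = TargetRegion("reg", "reg", 0, n, random_sequence(rng, n))
        with pytest.warns(UserWarning, match="coverage ratio"):
            pset = design_primer_set(region, DesignParams(spacing_bp=1000))
        assert pset.coverage_ratio <= 300

    def test_default_design_exceeds_coverage_ratio_300(self, small_region):
        pset = design_primer_set(small_region)
        assert pset.coverage_ratio > 300

    def test_alternate_strand_policy(self, small_region):
        pset = design_primer_set(
            small_region, DesignParams(strand_policy="alternate")
        )
        strands = [p.strand for p in pset.primers]
        assert "-" in strands and "+" in strands
        for p in pset.primers:
            expected = small_region.sequence[p.start : p.end]
            assert p.sequence == (expected if p.strand == "+" else revcomp(expected))

    def test_region_shorter_than_tile_rejected(self, rng):
        region = TargetRegion("r", "r", 0, 4000, random_sequence(rng, 4000))
        with pytest.raises(ValueError):
            design_primer_set(region)

    def test_snp_masked_bases_disqualify_candidates(self, rng):
        n = 30_000
        seq = random_sequence(rng, n)
        snps = [(int(p), int(p) + 1) for p in range(0, n, 97)]
        region = TargetRegion("reg", "reg", 0, n, seq, snp_mask=snps)
        pset = design_primer_set(region)
        snp_pos = {s for s, _ in snps}
        for p in pset.primers:
            assert not any(pos in snp_pos for pos in range(p.start, p.end))
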