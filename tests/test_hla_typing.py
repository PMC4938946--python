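"""Consensus calling, global alignment vs brute force, and allele typing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longcap.hla_typing import (
    AlleleDatabase,
    PileupColumn,
    call_allele,
    consensus_from_pileup,
    global_align,
    nw_score,
)

from conftest import random_sequence

dna8 = st.text(alphabet="ACGT", min_size=1, max_size=8)


def nw_oracle(a, b, match=1, mismatch=-1, gap=-1):
    """Exhaustive global-alignment recursion (no memoization)."""
    if not a:
        return gap * len(b)
    if not b:
        return gap * len(a)
    s = match if a[0] == b[0] else mismatch
    return max(
        nw_oracle(a[1:], b[1:], match, mismatch, gap) + s,
        nw_oracle(a[1:], b, match, mismatch, gap) + gap,
        nw_oracle(a, b[1:], match, mismatch, gap) + gap,
    )


class TestConsensus:
    def test_unanimous_column(self):
        assert consensus_from_pileup([PileupColumn(1, {"A": 10})]) == "A"

    def test_exact_tie_emits_n(self):
        assert consensus_from_pileup([PileupColumn(1, {"A": 5, "C": 5})]) == "N"

    def test_low_depth_emits_n(self):
        cols = [PileupColumn(1, {"A": 3}), PileupColumn(2, {"C": 10})]
        assert consensus_from_pileup(cols, min_depth=5) == "NC"

    def test_gap_majority_deletes_column(self):
        cols = [
            PileupColumn(1, {"A": 9}),
            PileupColumn(2, {"gap": 8, "C": 2}),
            PileupColumn(3, {"T": 9}),
        ]
        assert consensus_from_pileup(cols) == "AT"

    def test_random_pileups_match_argmax_oracle(self, rng):
        bases = ["A", "C", "G", "T", "gap"]
        cols = []
        expected = []
        for pos in range(300):
            counts = {b: int(c) for b, c in zip(bases, rng.integers(0, 20, 5))}
            cols.append(PileupColumn(pos, dict(counts)))
            depth = sum(counts.values())
            top = max(counts.values())
            winners = [b for b in bases if counts[b] == top]
            if depth < 3:
                expected.append("N")
            elif len(winners) > 1:
                expected.append("N")
            elif winners[0] != "gap":
                expected.append(winners[0])
        assert consensus_from_pileup(cols, min_depth=3) == "".join(expected)

    def test_empty_pileup_rejected(self):
        with pytest.raises(ValueError):
            consensus_from_pileup([])

    def test_unordered_columns_rejected(self):
        cols = [PileupColumn(5, {"A": 1}), PileupColumn(1, {"A": 1})]
        with pytest.raises(ValueError):
            consensus_from_pileup(cols)


class TestGlobalAlign:
    def test_identical_sequences(self):
        result = global_align("ACGTACGT", "ACGTACGT")
        assert result.score == 8.0
        assert result.percent_identity == 100.0

    def test_known_small_alignment(self):
        # optimal: ACGT / AC-T -> 3 matches, 1 gap = 3 - 1 = 2
        result = global_align("ACGT", "ACT")
        assert result.score == 2.0
        assert (result.aligned_a, result.aligned_b) == ("ACGT", "AC-T")

    @given(dna8, dna8)
    @settings(max_examples=60)
    def test_score_matches_exhaustive_enumeration(self, a, b):
        assert global_align(a, b).score == nw_oracle(a, b)

    @given(dna8, dna8)
    @settings(max_examples=30)
    def test_score_symmetric_for_symmetric_scoring(self, a, b):
        assert global_align(a, b).score == global_align(b, a).score

    def test_matches_biopython_aligner_on_long_sequences(self, rng):
        """Independent cross-check of the vectorized DP against Bio.Align."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -1
        aligner.extend_gap_score = -1
        for _ in range(5):
            a = random_sequence(rng, 300)
            b = random_sequence(rng, 310)
            assert nw_score(a, b) == aligner.score(a, b)

    def test_n_never_matches(self):
        result = global_align("ANA", "AAA")
        assert result.percent_identity < 100.0

    def test_traceback_alignment_is_consistent(self, rng):
        a, b = random_sequence(rng, 50), random_sequence(rng, 55)
        result = global_align(a, b)
        assert result.aligned_a.replace("-", "") == a
        assert result.aligned_b.replace("-", "") == b
        rescored = sum(
            1 if (x == y and x != "-" and x != "N") else -1
            for x, y in zip(result.aligned_a, result.aligned_b)
        )
        assert rescored == result.score

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")


def _mutate(rng, seq, rate):
    bases = "ACGT"
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = bases[(bases.index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def _db_fasta(out_dir, alleles):
    lines = []
    for i, (name, seq) in enumerate(alleles.items(), 1):
        lines.append(f">HLA:HLA{i:05d} {name} {len(seq)} bp")
        lines.append(seq)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "db.fa"
    path.write_text("\n".join(lines) + "\n")
    return path


class TestCallAllele:
    @pytest.fixture
    def db(self, tmp_path, rng):
        base = random_sequence(rng, 600)
        alleles = {
            "A*01:01:01:01": base,
            "A*02:01:01:01": _mutate(rng, base, 0.05),
            "A*03:01:01:01": _mutate(rng, base, 0.08),
            "B*07:02:01": random_sequence(rng, 600),
        }
        return alleles, AlleleDatabase.from_fasta(_db_fasta(tmp_path, alleles))

    def test_exact_match_has_full_identity(self, db):
        alleles, database = db
        result = call_allele(alleles["A*02:01:01:01"], database, "HLA-A")
        assert result.best_allele == "A*02:01:01:01"
        assert result.percent_identity == 100.0
        assert result.alignment_score >= result.runner_up_score

    def test_single_substitution_still_calls_source(self, db, rng):
        alleles, database = db
        truth = alleles["A*03:01:01:01"]
        query = truth[:300] + ("A" if truth[300] != "A" else "C") + truth[301:]
        result = call_allele(query, database, "A")
        assert result.best_allele == "A*03:01:01:01"
        assert result.percent_identity < 100.0

    def test_loci_are_partitioned(self, db):
        _, database = db
        assert set(database.alleles("B")) == {"B*07:02:01"}
        with pytest.raises(KeyError):
            database.alleles("DRB1")

    def test_recovers_source_allele_under_mutation(self, db, rng):
        alleles, database = db
        hits = 0
        for _ in range(20):
            query = _mutate(rng, alleles["A*02:01:01:01"], 0.01)
            result = call_allele(query, database, "A")
            hits += result.best_allele == "A*02:01:01:01"
        assert hits == 20

    def test_inserting_true_allele_never_lowers_its_rank(self, tmp_path, rng):
        base = random_sequence(rng, 400)
        query = _mutate(rng, base, 0.01)
        small = {"A*02:01": _mutate(rng, base, 0.06), "A*03:01": _mutate(rng, base, 0.07)}
        db_small = AlleleDatabase.from_fasta(_db_fasta(tmp_path / "s", small))
        score_without = call_allele(query, db_small, "A").alignment_score
        with_truth = dict(small)
        with_truth["A*01:01"] = base
        db_full = AlleleDatabase.from_fasta(_db_fasta(tmp_path / "f", with_truth))
        result = call_allele(query, db_full, "A")
        assert result.best_allele == "A*01:01"
        assert result.alignment_score >= score_without

    def test_deterministic_tie_break_prefers_smaller_name(self, tmp_path):
        seq = "ACGTACGTACGTACGTACGT"
        db = AlleleDatabase.from_fasta(
            _db_fasta(tmp_path, {"A*02:01": seq, "A*01:01": seq})
        )
        result = call_allele(seq, db, "A")
        assert result.best_allele == "A*01:01"
        assert result.runner_up == "A*02:01"

    def test_empty_locus_rejected(self, db):
        _, database = db
        with pytest.raises(KeyError):
            call_allele("ACGT", database, "DQB1")
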