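"""Global alignment, identity/similarity, and composition tables."""

from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormcal.conservation import (
    ProteinSeq,
    aa_composition,
    global_align,
    load_matrix,
    percent_identity,
    percent_similarity,
    read_fasta,
)

BLOSUM62 = load_matrix()


def oracle_score(a: str, b: str, gap_open=10.0, gap_extend=0.5) -> float:
    """Independent memoized recursion over (i, j, state) for the affine-gap
    global alignment score; no tables shared with the implementation."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        # state: 0 diagonal, 1 gap-in-b open, 2 gap-in-a open
        if i == 0 and j == 0:
            return 0.0 if state == 0 else -np.inf
        options = []
        if i > 0 and j > 0:
            sub = BLOSUM62[a[i - 1], b[j - 1]]
            if state == 0:
                options += [best(i - 1, j - 1, s) + sub for s in (0, 1, 2)]
        if i > 0 and state == 1:
            options.append(best(i - 1, j, 0) - gap_open)
            options.append(best(i - 1, j, 1) - gap_extend)
            options.append(best(i - 1, j, 2) - gap_open)
        if j > 0 and state == 2:
            options.append(best(i, j - 1, 0) - gap_open)
            options.append(best(i, j - 1, 1) - gap_open)
            options.append(best(i, j - 1, 2) - gap_extend)
        return max(options) if options else -np.inf

    return max(best(len(a), len(b), s) for s in (0, 1, 2))


class TestReadFasta:
    def test_basic_and_wrapped_and_lowercase(self, tmp_path):
        f = tmp_path / "a.fasta"
        f.write_text(">a description here\nMKV\n>b\nmkv\nlla\n>c\nMKVLLA\n")
        seqs = read_fasta(f)
        assert seqs[0].id == "a" and seqs[0].residues == "MKV"
        assert seqs[1].residues == "MKVLLA"  # wrapped == unwrapped
        assert seqs[1].residues == seqs[2].residues

    def test_empty_file_rejected(self, tmp_path):
        f = tmp_path / "empty.fasta"
        f.write_text("")
        with pytest.raises(ValueError):
            read_fasta(f)

    def test_illegal_characters_rejected(self, tmp_path):
        f = tmp_path / "bad.fasta"
        f.write_text(">a\nMKV1Z@\n")
        with pytest.raises(ValueError):
            read_fasta(f)

    def test_gap_characters_rejected(self, tmp_path):
        f = tmp_path / "gap.fasta"
        f.write_text(">a\nMK-V\n")
        with pytest.raises(ValueError, match="gap"):
            read_fasta(f)


class TestGlobalAlign:
    def test_identical_sequences_full_identity_no_gaps(self):
        s = ProteinSeq("a", "MKVLLAGHEW")
        res = global_align(s, s)
        assert res.percent_identity == pytest.approx(100.0)
        assert "-" not in res.aligned_a + res.aligned_b

    def test_textbook_pair_matches_oracle(self):
        a, b = ProteinSeq("a", "HEAGAWGHEE"), ProteinSeq("b", "PAWHEAE")
        res = global_align(a, b)
        assert res.score == pytest.approx(oracle_score(a.residues, b.residues))

    def test_reversed_sequence_not_fully_identical(self):
        s = ProteinSeq("a", "MKVLHAGREW")
        res = global_align(s, ProteinSeq("b", s.residues[::-1]))
        assert res.percent_identity < 100.0

    def test_score_symmetric_under_swap(self):
        rng = np.random.default_rng(0)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(10):
            a = ProteinSeq("a", "".join(rng.choice(list(aas), 12)))
            b = ProteinSeq("b", "".join(rng.choice(list(aas), 9)))
            assert global_align(a, b).score == pytest.approx(
                global_align(b, a).score)

    def test_dp_equals_bruteforce_recursion_on_short_4letter_pairs(self):
        """Every length combination up to 8 x 8 over a 4-letter alphabet."""
        rng = np.random.default_rng(1)
        alphabet = list("ACDE")
        for la in range(1, 9):
            for lb in range(1, 9):
                a = "".join(rng.choice(alphabet, la))
                b = "".join(rng.choice(alphabet, lb))
                res = global_align(ProteinSeq("a", a), ProteinSeq("b", b))
                assert res.score == pytest.approx(oracle_score(a, b)), (a, b)

    def test_agrees_with_established_aligner(self):
        from Bio import Align

        aligner = Align.PairwiseAligner(mode="global", open_gap_score=-10.0,
                                        extend_gap_score=-0.5)
        aligner.substitution_matrix = BLOSUM62
        rng = np.random.default_rng(2)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(10):
            a = "".join(rng.choice(list(aas), 30))
            b = "".join(rng.choice(list(aas), 25))
            res = global_align(ProteinSeq("a", a), ProteinSeq("b", b))
            assert res.score == pytest.approx(aligner.score(a, b))

    def test_memory_bound_guard(self):
        a = ProteinSeq("a", "M" * 1000)
        with pytest.raises(ValueError, match="max_cells"):
            global_align(a, a, max_cells=1000)

    def test_identity_similarity_invariants(self):
        rng = np.random.default_rng(3)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(10):
            a = ProteinSeq("a", "".join(rng.choice(list(aas), 20)))
            b = ProteinSeq("b", "".join(rng.choice(list(aas), 15)))
            res = global_align(a, b)
            assert res.percent_identity <= res.percent_similarity <= 100.0


class TestPercentIdentity:
    def test_identical_and_half_matching(self):
        s = ProteinSeq("a", "MKVLHAGREW")
        assert percent_identity(global_align(s, s)) == pytest.approx(100.0)
        half = ProteinSeq("b", "MKVLHWWWWW")  # 5 of 10 match, no gaps favoured
        res = global_align(s, half)
        matches = sum(x == y and x != "-" for x, y in
                      zip(res.aligned_a, res.aligned_b))
        assert res.percent_identity == pytest.approx(
            100 * matches / res.alignment_length)

    def test_column_count_matches_bruteforce_on_random_pairs(self):
        rng = np.random.default_rng(4)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(10):
            a = ProteinSeq("a", "".join(rng.choice(list(aas), 15)))
            b = ProteinSeq("b", "".join(rng.choice(list(aas), 12)))
            res = global_align(a, b)
            matches = sum(x == y and x != "-" for x, y in
                          zip(res.aligned_a, res.aligned_b))
            similar = sum(
                x != "-" and y != "-" and BLOSUM62[x, y] > 0
                for x, y in zip(res.aligned_a, res.aligned_b)
            )
            assert res.percent_identity == pytest.approx(
                100 * matches / res.alignment_length)
            assert percent_similarity(res) == pytest.approx(
                100 * similar / res.alignment_length)


class TestComposition:
    def test_worked_example(self):
        comp = aa_composition(ProteinSeq("a", "MMSS"))
        assert comp == {"M": 50.0, "S": 50.0}

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_percentages_sum_to_100(self, residues):
        comp = aa_composition(ProteinSeq("x", residues))
        assert sum(comp.values()) == pytest.approx(100.0)

    def test_invalid_sequences_rejected(self):
        with pytest.raises(ValueError):
            ProteinSeq("a", "")
        with pytest.raises(ValueError):
            ProteinSeq("a", "MK-V")
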