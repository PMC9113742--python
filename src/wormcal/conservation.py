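"""Protein conservation: global alignment identity/similarity and composition.

Supports the sequence-level comparisons behind the worm/human ryanodine
receptor and FKBP family claims: pairwise global alignment of protein
sequences under affine-gap BLOSUM62 scoring (the EMBOSS-needle default
parameterisation, gap open 10 / extend 0.5 — results shift with these, so
they are explicit), percent identity and similarity under both common
denominators, and amino-acid composition tables.

The aligner is a Gotoh three-state dynamic program with deterministic
tie-breaking (diagonal, then up, then left), written plainly so it can be
checked against an independent brute-force recursion in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "ProteinSeq",
    "AlignmentResult",
    "read_fasta",
    "global_align",
    "percent_identity",
    "percent_similarity",
    "aa_composition",
]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
_NEG = -1e30


@dataclass
class ProteinSeq:
    """A validated protein sequence (uppercase, 20-letter alphabet, X tolerated)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("sequence must be nonempty")
        self.residues = self.residues.upper()
        bad = set(self.residues) - AA_ALPHABET - {"X"}
        if bad:
            raise ValueError(f"illegal residue characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AlignmentResult:
    """A scored global alignment of two protein sequences."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float        # matches / alignment columns * 100
    percent_similarity: float      # positive-scoring pairs / columns * 100
    identity_over_shorter: float   # matches / len(shorter sequence) * 100
    alignment_length: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped sequences must have equal length")
        if not (self.percent_identity <= self.percent_similarity + 1e-9 <= 100 + 1e-9):
            raise ValueError("identity <= similarity <= 100 violated")


def read_fasta(path: str | Path) -> list[ProteinSeq]:
    """Read protein sequences; id is the first token of each header."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    out = []
    for rec in records:
        seq = str(rec.seq).replace(" ", "")
        if "-" in seq or "." in seq:
            raise ValueError(f"sequence {rec.id} contains gap characters")
        out.append(ProteinSeq(id=rec.id, residues=seq))
    return out


def _matrix_lookup(matrix) -> tuple[dict[str, int], np.ndarray]:
    alpha = {aa: i for i, aa in enumerate(matrix.alphabet)}
    return alpha, np.asarray(matrix)


def load_matrix(name: str = "BLOSUM62"):
    return substitution_matrices.load(name)


def global_align(a: ProteinSeq, b: ProteinSeq, matrix=None,
                 gap_open: float = 10.0, gap_extend: float = 0.5,
                 max_cells: int = 4_000_000) -> AlignmentResult:
    """Optimal global alignment under affine-gap scoring (Gotoh).

    A gap of length g costs ``gap_open + (g - 1) * gap_extend``.  Ties are
    broken deterministically: diagonal, then up (gap in b), then left
    (gap in a).  ``max_cells`` bounds the DP table; longer pairs raise with
    guidance rather than exhausting memory.
    """
    if matrix is None:
        matrix = load_matrix()
    n, m = len(a), len(b)
    if n * m > max_cells:
        raise ValueError(
            f"DP table {n} x {m} exceeds max_cells={max_cells}; raise max_cells "
            "explicitly if enough memory is available"
        )
    alpha, S = _matrix_lookup(matrix)
    ai = np.array([alpha[c] for c in a.residues])
    bi = np.array([alpha[c] for c in b.residues])
    sub = S[np.ix_(ai, bi)]  # (n, m) pair scores

    # states: 0 = M (diagonal), 1 = X (up, gap in b), 2 = Y (left, gap in a)
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    ptr = np.zeros((3, n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
        ptr[1, i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
        ptr[2, 0, j] = 0 if j == 1 else 2

    for i in range(1, n + 1):
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        srow = sub[i - 1]
        for j in range(1, m + 1):
            # M: extend all three states diagonally; priority M > X > Y
            best, state = Mp[j - 1], 0
            if Xp[j - 1] > best:
                best, state = Xp[j - 1], 1
            if Yp[j - 1] > best:
                best, state = Yp[j - 1], 2
            Mi[j] = best + srow[j - 1]
            ptr[0, i, j] = state
            # X: gap in b (move up)
            best, state = Mp[j] - gap_open, 0
            if Xp[j] - gap_extend > best:
                best, state = Xp[j] - gap_extend, 1
            if Yp[j] - gap_open > best:
                best, state = Yp[j] - gap_open, 2
            Xi[j] = best
            ptr[1, i, j] = state
            # Y: gap in a (move left)
            best, state = Mi[j - 1] - gap_open, 0
            if Xi[j - 1] - gap_open > best:
                best, state = Xi[j - 1] - gap_open, 1
            if Yi[j - 1] - gap_extend > best:
                best, state = Yi[j - 1] - gap_extend, 2
            Yi[j] = best
            ptr[2, i, j] = state

    finals = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(finals))  # argmax returns first max: M > X > Y priority
    score = float(finals[state])

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        prev = int(ptr[state, i, j])
        if state == 0:
            out_a.append(a.residues[i - 1])
            out_b.append(b.residues[j - 1])
            i -= 1
            j -= 1
        elif state == 1:
            out_a.append(a.residues[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b.residues[j - 1])
            j -= 1
        state = prev
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))

    length = len(aligned_a)
    matches = sum(x == y and x != "-" for x, y in zip(aligned_a, aligned_b))
    similar = sum(
        x != "-" and y != "-" and S[alpha[x], alpha[y]] > 0
        for x, y in zip(aligned_a, aligned_b)
    )
    return AlignmentResult(
        id_a=a.id,
        id_b=b.id,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        percent_identity=100.0 * matches / length,
        percent_similarity=100.0 * similar / length,
        identity_over_shorter=100.0 * matches / min(n, m),
        alignment_length=length,
    )


def percent_identity(alignment: AlignmentResult) -> float:
    """Identity over alignment columns (the primary denominator)."""
    return alignment.percent_identity


def percent_similarity(alignment: AlignmentResult) -> float:
    """Positive substitution-matrix pairs over alignment columns."""
    return alignment.percent_similarity


def aa_composition(seq: ProteinSeq) -> dict[str, float]:
    """Percent of each residue in the sequence; values sum to 100."""
    n = len(seq)
    counts: dict[str, int] = {}
    for c in seq.residues:
        counts[c] = counts.get(c, 0) + 1
    return {aa: 100.0 * k / n for aa, k in sorted(counts.items())}
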