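"""Pairwise alignment and identity metrics.

Optimal local (Smith-Waterman) and global (Needleman-Wunsch) alignment under
affine gap scoring, backed by :class:`Bio.Align.PairwiseAligner`. Gap
penalties use the BLAST convention: a gap of length k costs
``gap_open + k * gap_extend``.

Percent identity is, by default, matches over aligned columns (gaps count
against identity) — the single conservative definition used by both the
30-80 % mining window and the >98 % deduplication filter.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    n_matches: int
    n_columns: int
    mode: str

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")


def _make_aligner(
    mode: str,
    matrix: str | None,
    gap_open: float,
    gap_extend: float,
    match: float | None,
    mismatch: float | None,
) -> Align.PairwiseAligner:
    if mode not in ("local", "global"):
        raise ValueError(f"mode must be local or global, got {mode!r}")
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if match is not None:
        aligner.match_score = match
        aligner.mismatch_score = mismatch if mismatch is not None else -match
    else:
        try:
            aligner.substitution_matrix = substitution_matrices.load(matrix)
        except FileNotFoundError:
            raise ValueError(f"unknown substitution matrix {matrix!r}") from None
    # Biopython scores the first gap column with open_gap_score; BLAST's
    # open+k*extend convention therefore maps to -(open+extend), -extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def align(
    a: str,
    b: str,
    mode: str = "global",
    matrix: str | None = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    match: float | None = None,
    mismatch: float | None = None,
) -> AlignmentResult:
    """Optimal affine-gap alignment of two same-alphabet sequences.

    Pass ``match``/``mismatch`` instead of ``matrix`` for simple scoring
    (e.g. nucleotides). The returned traceback is Biopython's first optimal
    alignment, which is deterministic across runs.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(mode, matrix, gap_open, gap_extend, match, mismatch)
    alignments = aligner.align(a, b)
    try:
        aln = alignments[0]
    except IndexError:
        # a local alignment with best score 0 aligns nothing
        return AlignmentResult("", "", 0.0, 0, 0, mode)
    ga, gb = aln[0], aln[1]
    n_matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    return AlignmentResult(ga, gb, float(aln.score), n_matches, len(ga), mode)


def percent_identity(aln: AlignmentResult, denominator: str = "aligned_columns") -> float:
    """100 * matches / denominator, where the denominator is either the
    aligned column count (gaps penalized) or the shorter sequence length."""
    if denominator == "aligned_columns":
        denom = aln.n_columns
    elif denominator == "shorter_seq":
        denom = min(
            len(aln.aligned_a.replace("-", "")), len(aln.aligned_b.replace("-", ""))
        )
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError("zero-length identity denominator")
    return 100.0 * aln.n_matches / denom


def ungapped_window_identity(a: str, b: str) -> float:
    """Positionwise identity of two equal-length, ungapped windows."""
    if len(a) != len(b):
        raise ValueError(f"window lengths differ: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty windows")
    return 100.0 * sum(1 for x, y in zip(a, b) if x == y) / len(a)
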