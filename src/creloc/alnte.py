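"""Global affine-gap pairwise alignment, indel calling and windowed
identity tracks for consensus haplotype sequences.

The dynamic programme is Biopython's three-state global aligner; this
module fixes the scoring convention (a gap of length L costs
``gap_open + L * gap_extend``, with ``gap_open`` charged once per gap), a
mismatch-neutral score of 0 for N, and a reproducible indel placement:
every maximal gap run is shifted to the smallest sequence-A coordinate
among equal-scoring placements (left alignment), so planted or genotyped
indels get stable positions.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .intervals import GenomicInterval, merge_intervals

ALPHABET = "ACGTN"


@dataclass(frozen=True)
class AlignmentParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0  # charged once per gap
    gap_extend: float = -1.0  # per gap base

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")


@dataclass
class PairwiseAlignment:
    seq_a: str
    seq_b: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows must have equal length")
        if self.aligned_a.replace("-", "") != self.seq_a:
            raise ValueError("row A does not degap to input A")
        if self.aligned_b.replace("-", "") != self.seq_b:
            raise ValueError("row B does not degap to input B")

    def a_coordinate(self, column: int) -> int:
        """Number of A bases consumed before this alignment column."""
        return column - self.aligned_a[:column].count("-")


@dataclass(frozen=True)
class IndelCall:
    kind: str  # "insertion" (extra bases in B) or "deletion" (missing in B)
    position: int  # 0-based coordinate on sequence A
    length: int


def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array(alphabet=ALPHABET, dims=2)
    for x in ALPHABET:
        for y in ALPHABET:
            if "N" in (x, y):
                matrix[x, y] = 0.0
            else:
                matrix[x, y] = params.match if x == y else params.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    # Biopython charges open on the first gap base; convert from the
    # "open + L * extend" convention used here.
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _validate_sequence(name: str, seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"sequence {name} is empty")
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise ValueError(f"illegal symbols in {name}: {sorted(bad)}")
    return seq


def _left_normalize(row_gap: list[str], row_other: list[str]) -> None:
    """Shift each maximal gap run in ``row_gap`` as far left as possible
    without changing either degapped sequence or the alignment score."""
    n = len(row_gap)
    i = 0
    while i < n:
        if row_gap[i] != "-":
            i += 1
            continue
        s = i
        e = i
        while e < n and row_gap[e] == "-":
            e += 1
        while (
            s > 0
            and row_gap[s - 1] != "-"
            and row_other[s - 1] != "-"
            and row_other[s - 1] == row_other[e - 1]
        ):
            row_gap[e - 1] = row_gap[s - 1]
            row_gap[s - 1] = "-"
            s -= 1
            e -= 1
        i = e + 1


def global_align(
    seq_a: str, seq_b: str, params: AlignmentParams | None = None
) -> PairwiseAlignment:
    """Optimal global alignment under affine gap costs.

    Ties between equal-scoring traceback paths are resolved by taking the
    aligner's first reported path and then left-aligning all gap runs.
    """
    if params is None:
        params = AlignmentParams()
    seq_a = _validate_sequence("A", seq_a)
    seq_b = _validate_sequence("B", seq_b)
    aligner = _aligner(params)
    alignment = aligner.align(seq_a, seq_b)[0]
    row_a = list(alignment[0])
    row_b = list(alignment[1])
    # normalise gap placement: runs in B first, then runs in A
    _left_normalize(row_b, row_a)
    _left_normalize(row_a, row_b)
    return PairwiseAlignment(
        seq_a, seq_b, "".join(row_a), "".join(row_b), float(alignment.score)
    )


def alignment_score(aligned_a: str, aligned_b: str, params: AlignmentParams | None = None) -> float:
    """Score an explicit alignment (gap runs cost open + L * extend)."""
    if params is None:
        params = AlignmentParams()
    score = 0.0
    for row in (aligned_a, aligned_b):
        in_gap = False
        for ch in row:
            if ch == "-":
                if not in_gap:
                    score += params.gap_open
                score += params.gap_extend
                in_gap = True
            else:
                in_gap = False
    for x, y in zip(aligned_a, aligned_b):
        if "-" in (x, y):
            continue
        if "N" in (x, y):
            continue
        score += params.match if x == y else params.mismatch
    return score


def call_indels(
    alignment: PairwiseAlignment, min_len: int = 1
) -> list[IndelCall]:
    """Maximal gap runs as indel calls with sequence-A coordinates.

    A gap run in row A means B carries extra bases (an insertion in B,
    positioned at the A coordinate where it occurs); a run in row B means
    B is missing bases (a deletion in B, positioned at the first deleted
    A base).  Runs shorter than ``min_len`` are suppressed.
    """
    calls: list[IndelCall] = []
    col = 0
    n = len(alignment.aligned_a)
    while col < n:
        a_ch = alignment.aligned_a[col]
        b_ch = alignment.aligned_b[col]
        if a_ch == "-" or b_ch == "-":
            row = alignment.aligned_a if a_ch == "-" else alignment.aligned_b
            start = col
            while col < n and row[col] == "-":
                col += 1
            length = col - start
            if length >= min_len:
                calls.append(
                    IndelCall(
                        "insertion" if a_ch == "-" else "deletion",
                        alignment.a_coordinate(start),
                        length,
                    )
                )
        else:
            col += 1
    return calls


def windowed_identity(
    alignment: PairwiseAlignment,
    window_bp: int = 100,
    threshold: float = 0.75,
    scaffold: str = "seqA",
) -> tuple[list[float], list[GenomicInterval], list[GenomicInterval]]:
    """Fraction of match columns per window of alignment columns (gap
    columns count as mismatch), with windows reported in A coordinates,
    plus the merged intervals where identity >= ``threshold``."""
    n = len(alignment.aligned_a)
    identities: list[float] = []
    windows: list[GenomicInterval] = []
    for start in range(0, n, window_bp):
        end = min(start + window_bp, n)
        cols = range(start, end)
        matches = sum(
            1
            for c in cols
            if alignment.aligned_a[c] == alignment.aligned_b[c]
            and alignment.aligned_a[c] != "-"
        )
        identities.append(matches / (end - start))
        a_start = alignment.a_coordinate(start)
        a_end = alignment.a_coordinate(end)
        if a_end == a_start:  # window fully inside an A gap
            a_end = a_start + 1
        windows.append(GenomicInterval(scaffold, a_start, a_end))
    above = [
        win.with_score(ident)
        for win, ident in zip(windows, identities)
        if ident >= threshold
    ]
    return identities, windows, merge_intervals(above, gap=0)
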