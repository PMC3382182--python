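"""Thin wrappers around Bio.Align.PairwiseAligner with the scoring schemes
used throughout the package, plus column-level statistics extraction.

Identity convention (used everywhere): the denominator is the number of
alignment columns between the first and last column where both sequences
have a residue — end gaps are excluded, internal gaps count as mismatch
columns.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices


def dna_local_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -5
    a.extend_gap_score = -2
    return a


def dna_glocal_aligner() -> Align.PairwiseAligner:
    """Query-global, target-end-gap-free: full read against a reference window."""
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -5
    a.extend_gap_score = -2
    a.end_deletion_score = 0  # reference-window overhangs are free
    return a


def protein_global_aligner() -> Align.PairwiseAligner:
    """End-gap-free global (needle-style) protein alignment under BLOSUM62."""
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11
    a.extend_gap_score = -1
    a.end_gap_score = 0
    return a


def protein_local_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11
    a.extend_gap_score = -1
    return a


@dataclass(frozen=True)
class PairStats:
    identity: float  # matches / columns (end gaps excluded)
    length: int  # columns between first and last doubly-aligned column
    matches: int
    score: float
    target_range: tuple[int, int]  # on target, end gaps excluded
    query_range: tuple[int, int]


def alignment_stats(alignment) -> PairStats:
    """Column statistics for one Bio.Align.Alignment.

    Computed from the aligned block coordinates, so local and end-gap-free
    global alignments are handled uniformly: columns run from the first to
    the last doubly-aligned block, internal gaps count as (mismatch)
    columns, end gaps are excluded."""
    t_blocks, q_blocks = alignment.aligned
    if len(t_blocks) == 0:
        return PairStats(0.0, 0, 0, float(alignment.score), (0, 0), (0, 0))
    target = str(alignment.target)
    query = str(alignment.query)
    matches = 0
    cols = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for i in range(te - ts):
            if target[ts + i] == query[qs + i]:
                matches += 1
        cols += te - ts
    for bi in range(1, len(t_blocks)):
        cols += int(t_blocks[bi][0] - t_blocks[bi - 1][1])
        cols += int(q_blocks[bi][0] - q_blocks[bi - 1][1])
    return PairStats(
        identity=matches / cols if cols else 0.0,
        length=cols,
        matches=matches,
        score=float(alignment.score),
        target_range=(int(t_blocks[0][0]), int(t_blocks[-1][1])),
        query_range=(int(q_blocks[0][0]), int(q_blocks[-1][1])),
    )


def align_pair(a: str, b: str, aligner: Align.PairwiseAligner) -> PairStats:
    """Best alignment of target `a` vs query `b`, summarized."""
    return alignment_stats(aligner.align(a, b)[0])
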