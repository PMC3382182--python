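"""Six-frame translated local search of DNA queries against a protein DB.

Each frame translation is split at stop codons; segments are pre-filtered
with a shared amino-acid k-mer screen and candidates are aligned with a
local BLOSUM62 alignment.  Hits below `min_score` are suppressed.  Query
coordinates are recorded as forward-strand codon-start positions so hits
from different frames share one amino-acid-scale coordinate system, which
is what the non-redundant merge operates on.  Pre-computed 12-column
tabular hits can be imported in place of the internal search.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

from picomet.align import protein_local_aligner
from picomet.refmap.mapper import revcomp
from picomet.taxassign.db import ProteinDB

DEFAULT_MIN_SCORE = 35.0
_SEED_K = 4


@dataclass(frozen=True)
class LocalHit:
    query_id: str
    subject_id: str
    frame: int  # +-1, +-2, +-3
    q_start: int  # forward-strand nt coordinates, half-open
    q_end: int
    s_start: int  # subject aa coordinates, half-open
    s_end: int
    matches: int
    columns: int
    score: float
    # codon-start positions (forward strand) covered / matched; None for imported hits
    covered_positions: frozenset[int] | None = None
    match_positions: frozenset[int] | None = None

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


class SeedIndex:
    """Amino-acid k-mer -> subject ids sharing it."""

    def __init__(self, db: ProteinDB, k: int = _SEED_K):
        self.k = k
        self.table: dict[str, set[str]] = defaultdict(set)
        for pid, prot in db.proteins.items():
            s = prot.sequence
            for i in range(len(s) - k + 1):
                self.table[s[i : i + k]].add(pid)

    def candidates(self, peptide: str) -> set[str]:
        out: set[str] = set()
        k = self.k
        for i in range(len(peptide) - k + 1):
            hits = self.table.get(peptide[i : i + k])
            if hits:
                out |= hits
        return out


def _frames(dna: str) -> Iterable[tuple[int, int, str]]:
    """Yield (frame, offset, peptide) for all six frames.  `offset` is the
    nt offset of the first codon on the frame's own strand."""
    for strand_seq, sign in ((dna, 1), (revcomp(dna), -1)):
        for off in range(3):
            usable = (len(strand_seq) - off) // 3 * 3
            if usable < 3:
                continue
            pep = str(Seq(strand_seq[off : off + usable]).translate())
            yield sign * (off + 1), off, pep


def _codon_start_forward(frame: int, offset: int, aa_index: int, qlen: int) -> int:
    """Forward-strand position of the first nt of codon `aa_index`."""
    if frame > 0:
        return offset + 3 * aa_index
    return qlen - (offset + 3 * aa_index) - 3


def translated_search(
    query_id: str,
    query_dna: str,
    db: ProteinDB,
    min_score: float = DEFAULT_MIN_SCORE,
    seed_index: SeedIndex | None = None,
    min_segment_len: int = 8,
) -> list[LocalHit]:
    """Search one DNA query against all database proteins."""
    if len(query_dna) < 3:
        raise ValueError("query shorter than one codon")
    index = seed_index if seed_index is not None else SeedIndex(db)
    aligner = protein_local_aligner()
    qlen = len(query_dna)
    hits: list[LocalHit] = []
    for frame, offset, pep in _frames(query_dna):
        seg_start = 0
        for segment in pep.split("*"):
            if len(segment) >= min_segment_len:
                for sid in index.candidates(segment):
                    subject = db.proteins[sid].sequence
                    try:
                        alignment = aligner.align(subject, segment)[0]
                    except (IndexError, OverflowError):
                        continue
                    if alignment.score < min_score:
                        continue
                    hit = _hit_from_alignment(
                        alignment, query_id, sid, frame, offset, seg_start, qlen, subject, segment
                    )
                    if hit is not None:
                        hits.append(hit)
            seg_start += len(segment) + 1
    hits.sort(key=lambda h: (-h.score, h.subject_id, h.frame))
    return hits


def _hit_from_alignment(
    alignment, query_id, subject_id, frame, offset, seg_start, qlen, subject, segment
) -> LocalHit | None:
    s_blocks, q_blocks = alignment.aligned
    if len(s_blocks) == 0:
        return None
    covered: set[int] = set()
    matched: set[int] = set()
    matches = 0
    columns = 0
    for (ss, se), (qs, qe) in zip(s_blocks, q_blocks):
        for i in range(se - ss):
            aa_q = seg_start + qs + i
            pos = _codon_start_forward(frame, offset, aa_q, qlen)
            covered.add(pos)
            columns += 1
            if subject[ss + i] == segment[qs + i]:
                matches += 1
                matched.add(pos)
    # internal gap columns count toward alignment length
    for bi in range(1, len(s_blocks)):
        columns += int(s_blocks[bi][0] - s_blocks[bi - 1][1])
        columns += int(q_blocks[bi][0] - q_blocks[bi - 1][1])
    aa_q_first = seg_start + int(q_blocks[0][0])
    aa_q_last = seg_start + int(q_blocks[-1][1]) - 1
    nt_positions = [
        _codon_start_forward(frame, offset, aa_q_first, qlen),
        _codon_start_forward(frame, offset, aa_q_last, qlen),
    ]
    q_start = min(nt_positions)
    q_end = max(nt_positions) + 3
    return LocalHit(
        query_id=query_id,
        subject_id=subject_id,
        frame=frame,
        q_start=q_start,
        q_end=q_end,
        s_start=int(s_blocks[0][0]),
        s_end=int(s_blocks[-1][1]),
        matches=matches,
        columns=columns,
        score=float(alignment.score),
        covered_positions=frozenset(covered),
        match_positions=frozenset(matched),
    )


def read_tabular_hits(path: str, query_lengths: dict[str, int] | None = None) -> list[LocalHit]:
    """Import 12-column tabular hits:
    qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore.

    Coordinates are 1-based inclusive in the file.  Matches are recomputed
    from pident x length.  Per-position profiles are unavailable for
    imported hits, so merges fall back to per-hit uniform match density."""
    hits: list[LocalHit] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            qid, sid = f[0], f[1]
            pident, length = float(f[2]), int(f[3])
            qs, qe, ss, se = int(f[6]), int(f[7]), int(f[8]), int(f[9])
            score = float(f[11])
            reverse = qs > qe
            q_start, q_end = (qe - 1, qs) if reverse else (qs - 1, qe)
            frame = -1 if reverse else 1  # dialect carries strand, not the exact frame
            hits.append(
                LocalHit(
                    query_id=qid,
                    subject_id=sid,
                    frame=frame,
                    q_start=q_start,
                    q_end=q_end,
                    s_start=ss - 1,
                    s_end=se,
                    matches=int(round(pident / 100.0 * length)),
                    columns=length,
                    score=score,
                )
            )
    return hits
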