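"""Greedy seed-and-extend read mapping against a small reference.

A k-mer (default k=14) exact-seed index votes for (chromosome, diagonal)
candidates; candidate loci are re-aligned with a banded-window
query-global alignment and the single best location per read is kept
(identity >= 0.90 over >= 40 aligned columns by default, mirroring
common 454-assembler overlap thresholds).  Ties break to the
lexicographically lowest (chromosome, position).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

from picomet.align import dna_glocal_aligner
from picomet.synthdata.reads import ReadRecord

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class ReadAlignment:
    """One read placed on the reference.  `seq` is the read in mapped
    orientation; `cigar` uses ops M (aligned column run), I (insertion to
    reference), D (deletion from reference), S (soft clip)."""

    read_id: str
    chrom: str
    ref_start: int
    strand: str
    cigar: list[tuple[str, int]]
    seq: str
    mismatches: int
    score: float
    identity: float
    aligned_len: int

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.cigar if op in "MD")

    def columns(self) -> Iterator[tuple[int, str]]:
        """Yield (reference position, read base or '-') for every
        reference-consuming column; insertions are skipped."""
        rpos = self.ref_start
        qpos = 0
        for op, n in self.cigar:
            if op == "M":
                for i in range(n):
                    yield rpos + i, self.seq[qpos + i]
                rpos += n
                qpos += n
            elif op == "D":
                for i in range(n):
                    yield rpos + i, "-"
                rpos += n
            elif op in ("I", "S"):
                qpos += n

    def validate(self, chrom_len: int) -> None:
        if not 0 <= self.ref_start < self.ref_end <= chrom_len:
            raise ValueError(f"alignment of {self.read_id} outside chromosome bounds")
        if self.mismatches > self.aligned_len:
            raise ValueError(f"alignment of {self.read_id}: mismatches exceed columns")


@dataclass
class MappingResult:
    alignments: list[ReadAlignment] = field(default_factory=list)
    unmapped: list[str] = field(default_factory=list)


class ReferenceIndex:
    """Exact k-mer seed table over a set of chromosomes."""

    def __init__(self, sequences: Mapping[str, str], k: int = 14, max_occurrences: int = 200):
        if not sequences or sum(len(s) for s in sequences.values()) == 0:
            raise ValueError("empty reference")
        self.k = k
        self.sequences = dict(sequences)
        self.chrom_ids = sorted(sequences)
        table: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for ci, cid in enumerate(self.chrom_ids):
            seq = sequences[cid]
            for i in range(len(seq) - k + 1):
                table[seq[i : i + k]].append((ci, i))
        # drop hyper-repetitive seeds
        self.table = {km: v for km, v in table.items() if len(v) <= max_occurrences}

    def candidates(self, read: str, stride: int = 7, bin_width: int = 32, top: int = 4) -> list[tuple[int, int]]:
        """Vote for (chrom index, approximate diagonal) bins; return up to
        `top` candidate (chrom index, ref start estimate) pairs."""
        votes: Counter[tuple[int, int]] = Counter()
        diag_min: dict[tuple[int, int], int] = {}
        k = self.k
        for i in range(0, max(len(read) - k + 1, 1), stride):
            hits = self.table.get(read[i : i + k])
            if not hits:
                continue
            for ci, p in hits:
                d = p - i
                key = (ci, d // bin_width)
                votes[key] += 1
                if key not in diag_min or d < diag_min[key]:
                    diag_min[key] = d
        if not votes:
            return []
        best = votes.most_common()
        thresh = max(2, best[0][1] // 4)
        picked = [key for key, v in best if v >= thresh][:top] or [best[0][0]]
        return [(ci, diag_min[(ci, b)]) for ci, b in picked]


def _cigar_from_alignment(alignment, read_len: int) -> tuple[list[tuple[str, int]], int]:
    """Convert a Bio.Align alignment (target=window, query=read) into a
    cigar plus the window-relative reference start."""
    t_blocks, q_blocks = alignment.aligned
    cigar: list[tuple[str, int]] = []
    q0 = int(q_blocks[0][0])
    if q0 > 0:
        cigar.append(("S", q0))
    for bi in range(len(t_blocks)):
        if bi > 0:
            dt = int(t_blocks[bi][0] - t_blocks[bi - 1][1])
            dq = int(q_blocks[bi][0] - q_blocks[bi - 1][1])
            if dq > 0:
                cigar.append(("I", dq))
            if dt > 0:
                cigar.append(("D", dt))
        cigar.append(("M", int(t_blocks[bi][1] - t_blocks[bi][0])))
    q_end = int(q_blocks[-1][1])
    if q_end < read_len:
        cigar.append(("S", read_len - q_end))
    return cigar, int(t_blocks[0][0])


def _align_candidate(
    aligner, window: str, read: str
) -> tuple[list[tuple[str, int]], int, int, int, float] | None:
    try:
        alignment = aligner.align(window, read)[0]
    except (IndexError, OverflowError):
        return None
    if len(alignment.aligned[0]) == 0:
        return None
    cigar, w_start = _cigar_from_alignment(alignment, len(read))
    # count matches over M runs
    matches = 0
    columns = 0
    rpos, qpos = w_start, 0
    for op, n in cigar:
        if op == "M":
            for i in range(n):
                if window[rpos + i] == read[qpos + i]:
                    matches += 1
            columns += n
            rpos += n
            qpos += n
        elif op == "D":
            columns += n
            rpos += n
        elif op == "I":
            columns += n
            qpos += n
        else:
            qpos += n
    return cigar, w_start, matches, columns, float(alignment.score)


def map_reads(
    reads: Sequence[ReadRecord],
    reference: Mapping[str, str] | "ReferenceIndex",
    min_identity: float = 0.90,
    min_match_len: int = 40,
    k: int = 14,
    pad: int = 40,
) -> MappingResult:
    """Map each read to its single best reference location.

    `reference` may be a chromosome-id -> sequence mapping or a prebuilt
    :class:`ReferenceIndex` (reused across calls)."""
    index = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference, k=k)
    aligner = dna_glocal_aligner()
    result = MappingResult()
    for rec in reads:
        best: tuple | None = None  # (-score, chrom, pos, payload)
        for strand, seq in (("+", rec.sequence), ("-", revcomp(rec.sequence))):
            for ci, diag in index.candidates(seq):
                cid = index.chrom_ids[ci]
                ref_seq = index.sequences[cid]
                w_lo = max(diag - pad, 0)
                w_hi = min(diag + len(seq) + pad, len(ref_seq))
                if w_hi - w_lo < min_match_len:
                    continue
                hit = _align_candidate(aligner, ref_seq[w_lo:w_hi], seq)
                if hit is None:
                    continue
                cigar, w_start, matches, columns, score = hit
                if columns < min_match_len or matches / columns < min_identity:
                    continue
                ref_start = w_lo + w_start
                key = (-score, cid, ref_start)
                if best is None or key < best[0]:
                    best = (
                        key,
                        ReadAlignment(
                            read_id=rec.id,
                            chrom=cid,
                            ref_start=ref_start,
                            strand=strand,
                            cigar=cigar,
                            seq=seq,
                            mismatches=columns - matches,
                            score=score,
                            identity=matches / columns,
                            aligned_len=columns,
                        ),
                    )
        if best is None:
            result.unmapped.append(rec.id)
        else:
            aln = best[1]
            aln.validate(len(index.sequences[aln.chrom]))
            result.alignments.append(aln)
    return result
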