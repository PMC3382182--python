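"""Pileup columns over a reference region from read alignments."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from picomet.refmap.mapper import ReadAlignment

BASES = ("A", "C", "G", "T", "-")


@dataclass
class PileupColumn:
    chrom: str
    position: int
    ref_base: str
    counts: dict[str, int] = field(default_factory=lambda: {b: 0 for b in BASES})

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


def pileup(
    alignments: Sequence[ReadAlignment],
    sequences: Mapping[str, str],
    region: tuple[str, int, int],
) -> list[PileupColumn]:
    """Per-column base counts over `region` = (chrom, start, end).

    Deletions are tallied in the gap channel; insertions do not create
    columns."""
    chrom, start, end = region
    if chrom not in sequences:
        raise ValueError(f"unknown chromosome {chrom!r}")
    seq = sequences[chrom]
    if not 0 <= start < end <= len(seq):
        raise ValueError(f"region [{start}, {end}) outside chromosome {chrom} (length {len(seq)})")
    cols = [PileupColumn(chrom, pos, seq[pos]) for pos in range(start, end)]
    for aln in alignments:
        if aln.chrom != chrom or aln.ref_end <= start or aln.ref_start >= end:
            continue
        for rpos, base in aln.columns():
            if start <= rpos < end and base in BASES:
                cols[rpos - start].counts[base] += 1
    return cols
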