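"""Screen contigs for rRNA genes by nucleotide local alignment; hits
longer than a length floor (default 200 bp) are retained."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from picomet.align import align_pair, dna_local_aligner


@dataclass(frozen=True)
class RrnaHit:
    contig_id: str
    rrna_id: str
    length: int
    identity: float
    contig_range: tuple[int, int]
    score: float


def screen_rrna(
    contigs: Mapping[str, str],
    rrna_refs: Mapping[str, str],
    min_hit_len: int = 200,
    min_identity: float = 0.7,
) -> list[RrnaHit]:
    """Best local hit per (contig, rRNA reference); only hits with aligned
    length > `min_hit_len` (and identity >= `min_identity`, guarding
    against spurious low-complexity alignments) are reported."""
    aligner = dna_local_aligner()
    out: list[RrnaHit] = []
    for cid, cseq in sorted(contigs.items()):
        for rid, rseq in sorted(rrna_refs.items()):
            stats = align_pair(cseq, rseq, aligner)
            if stats.length > min_hit_len and stats.identity >= min_identity:
                out.append(
                    RrnaHit(cid, rid, stats.length, stats.identity, stats.target_range, stats.score)
                )
    return out
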