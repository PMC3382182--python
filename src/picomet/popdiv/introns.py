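"""Intron presence/absence genotyping from junction-spanning reads.

Each read is aligned to both variants of a region (with and without the
intron).  The two variants must be identical apart from one inserted
block; the insertion interval is located automatically from their common
prefix/suffix.  A read is informative only if it spans an insertion
junction by at least `junction_support` bp on each side on its
better-scoring variant; its status is the variant with the strictly
higher alignment score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from picomet.align import align_pair, dna_local_aligner
from picomet.refmap.mapper import revcomp
from picomet.synthdata.reads import ReadRecord

JUNCTION_SUPPORT = 20


@dataclass(frozen=True)
class ReadStatus:
    read_id: str
    status: str  # intron+ | intron- | uninformative


@dataclass
class IntronCall:
    feature: str
    junction: int  # insertion point on the intron-less variant
    intron_length: int
    statuses: list[ReadStatus]

    @property
    def n_plus(self) -> int:
        return sum(1 for s in self.statuses if s.status == "intron+")

    @property
    def n_minus(self) -> int:
        return sum(1 for s in self.statuses if s.status == "intron-")

    @property
    def n_informative(self) -> int:
        return self.n_plus + self.n_minus

    @property
    def plus_fraction(self) -> float:
        n = self.n_informative
        return self.n_plus / n if n else float("nan")

    @property
    def majority(self) -> str:
        if self.n_informative == 0:
            return "uninformative"
        return "intron+" if self.n_plus * 2 >= self.n_informative else "intron-"


def locate_insertion(without: str, with_intron: str) -> tuple[int, int]:
    """(insertion point on `without`, intron length) from the common
    prefix/suffix of the two variants."""
    if len(with_intron) <= len(without):
        raise ValueError("intron-bearing variant must be longer")
    ilen = len(with_intron) - len(without)
    pre = 0
    while pre < len(without) and without[pre] == with_intron[pre]:
        pre += 1
    suf = 0
    while suf < len(without) - pre and without[-1 - suf] == with_intron[-1 - suf]:
        suf += 1
    if pre + suf < len(without):
        raise ValueError("variants differ outside a single inserted block")
    return min(pre, len(without) - suf) if pre + suf > len(without) else pre, ilen


def call_introns(
    reads: Sequence[ReadRecord],
    ref_without_intron: str,
    ref_with_intron: str,
    feature: str,
    junction_support: int = JUNCTION_SUPPORT,
) -> IntronCall:
    """Classify reads as intron+/intron-/uninformative for one feature."""
    if ref_without_intron == ref_with_intron:
        raise ValueError("the two reference variants are identical")
    junction, ilen = locate_insertion(ref_without_intron, ref_with_intron)
    aligner = dna_local_aligner()
    statuses: list[ReadStatus] = []
    for rec in reads:
        best = None  # (score, label, stats)
        for seq in (rec.sequence, revcomp(rec.sequence)):
            s_without = align_pair(ref_without_intron, seq, aligner)
            s_with = align_pair(ref_with_intron, seq, aligner)
            for label, st in (("intron-", s_without), ("intron+", s_with)):
                if best is None or st.score > best[0]:
                    best = (st.score, label, st, s_without.score, s_with.score)
        _, label, st, score_without, score_with = best
        if score_without == score_with:
            statuses.append(ReadStatus(rec.id, "uninformative"))
            continue
        lo, hi = st.target_range
        if label == "intron-":
            spans = lo <= junction - junction_support and hi >= junction + junction_support
        else:
            left = (junction, junction + ilen)  # exon|intron and intron|exon junctions
            spans = any(
                lo <= j - junction_support and hi >= j + junction_support for j in left
            )
        statuses.append(ReadStatus(rec.id, label if spans else "uninformative"))
    return IntronCall(feature=feature, junction=junction, intron_length=ilen, statuses=statuses)
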