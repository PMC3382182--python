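"""Condensation of local hits into one non-redundant global alignment
per query-subject pair.

L is the size of the union of query positions covered by any hit
(amino-acid scale: codon-start positions).  Positions covered by several
hits are counted once and credited to the highest-scoring hit covering
them, so I is the match fraction over the union.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

from picomet.taxassign.search import LocalHit


@dataclass(frozen=True)
class MergedAlignment:
    query_id: str
    subject_id: str
    length: int  # L, amino-acid positions
    identity: float  # I
    score: float  # sum of owning-hit score contributions (ranking key)
    n_hits: int


def merge_hits(hits: Sequence[LocalHit]) -> MergedAlignment:
    """Merge local hits for one (query, subject) pair."""
    if not hits:
        raise ValueError("no hits to merge")
    qids = {h.query_id for h in hits}
    sids = {h.subject_id for h in hits}
    if len(qids) != 1 or len(sids) != 1:
        raise ValueError("hits span multiple query/subject pairs")

    ordered = sorted(hits, key=lambda h: -h.score)
    owner: dict[int, LocalHit] = {}
    for h in ordered:
        positions = (
            h.covered_positions
            if h.covered_positions is not None
            else range(h.q_start, h.q_end, 3)
        )
        for pos in positions:
            if pos not in owner:
                owner[pos] = h
    length = len(owner)
    match_mass = 0.0
    for pos, h in owner.items():
        if h.match_positions is not None:
            match_mass += 1.0 if pos in h.match_positions else 0.0
        else:  # imported hit: uniform match density
            match_mass += h.matches / h.columns if h.columns else 0.0
    identity = match_mass / length if length else 0.0
    score = sum(h.score for h in {id(h): h for h in owner.values()}.values())
    return MergedAlignment(
        query_id=hits[0].query_id,
        subject_id=hits[0].subject_id,
        length=length,
        identity=identity,
        score=score,
        n_hits=len(hits),
    )


def merge_by_subject(hits: Sequence[LocalHit]) -> list[MergedAlignment]:
    """Merge all hits of one query, grouped by subject, best score first."""
    groups: dict[str, list[LocalHit]] = defaultdict(list)
    for h in hits:
        groups[h.subject_id].append(h)
    merged = [merge_hits(g) for g in groups.values()]
    merged.sort(key=lambda m: (-m.score, m.subject_id))
    return merged
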