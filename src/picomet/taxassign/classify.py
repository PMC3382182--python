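"""Hierarchical genus -> class -> best-hit-default assignment."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from picomet.taxassign.db import ProteinDB
from picomet.taxassign.merge import MergedAlignment, merge_by_subject
from picomet.taxassign.search import LocalHit, SeedIndex, translated_search
from picomet.taxassign.thresholds import ThresholdMatrix


@dataclass(frozen=True)
class Assignment:
    query_id: str
    level: str  # genus | class | bbh-default | unassigned
    taxon: str | None
    subject_id: str | None
    identity: float
    length: int
    thresholds_used: tuple | None = None


def assign(
    query_id: str,
    merged: Sequence[MergedAlignment],
    matrix: ThresholdMatrix,
    db: ProteinDB,
) -> Assignment:
    """Assign one query from its merged alignments.

    The best merged subject (highest merged score, ties to lowest subject
    id) is evaluated against its per-protein thresholds: genus rank if
    I >= I_min_genus and L >= L_min_genus, else class rank if both class
    thresholds are met, else the best hit's own taxon under the default
    floor (80% identity over 50 aa), else unassigned."""
    if not merged:
        return Assignment(query_id, "unassigned", None, None, 0.0, 0)
    best = min(merged, key=lambda m: (-m.score, m.subject_id))
    prot = db.proteins[best.subject_id]
    row = matrix[best.subject_id] if best.subject_id in matrix else None
    I, L = best.identity, best.length
    if row is not None and not row.specific:
        if (
            row.i_min_genus is not None
            and I >= row.i_min_genus
            and L >= row.l_min_genus
        ):
            return Assignment(
                query_id, "genus", prot.genus, prot.id, I, L, (row.i_min_genus, row.l_min_genus)
            )
        if I >= row.i_min_class and L >= row.l_min_class:
            return Assignment(
                query_id, "class", prot.class_, prot.id, I, L, (row.i_min_class, row.l_min_class)
            )
    if I >= matrix.default_identity and L >= matrix.default_length:
        return Assignment(
            query_id,
            "bbh-default",
            prot.genus,
            prot.id,
            I,
            L,
            (matrix.default_identity, matrix.default_length),
        )
    return Assignment(query_id, "unassigned", None, prot.id, I, L)


def classify_query(
    query_id: str,
    query_dna: str,
    db: ProteinDB,
    matrix: ThresholdMatrix,
    min_score: float = 35.0,
    seed_index: SeedIndex | None = None,
    hits: Sequence[LocalHit] | None = None,
) -> Assignment:
    """Search (or accept pre-computed hits), merge, and assign one query."""
    if hits is None:
        hits = translated_search(query_id, query_dna, db, min_score=min_score, seed_index=seed_index)
    merged = merge_by_subject(hits)
    return assign(query_id, merged, matrix, db)


def write_assignments_tsv(assignments: Sequence[Assignment], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("query\tlevel\ttaxon\tidentity\tlength\tsubject\n")
        for a in assignments:
            fh.write(
                f"{a.query_id}\t{a.level}\t{a.taxon or ''}\t{a.identity:.4f}\t{a.length}\t{a.subject_id or ''}\n"
            )
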