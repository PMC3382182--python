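"""Minimal lowest-common-ancestor read/contig assignment with score and
support filters (min score, top-percent, min support)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence


@dataclass
class Taxonomy:
    """Rooted taxonomy as child -> parent; the root maps to itself."""

    parent: dict[str, str]
    root: str = "cellular organism"

    def __post_init__(self) -> None:
        self.parent.setdefault(self.root, self.root)
        for child, par in self.parent.items():
            if par not in self.parent:
                raise ValueError(f"taxon {child!r} has unknown parent {par!r}")

    def path(self, taxon: str) -> list[str]:
        if taxon not in self.parent:
            raise ValueError(f"unknown taxon {taxon!r}")
        out = [taxon]
        while out[-1] != self.root:
            out.append(self.parent[out[-1]])
        return out[::-1]  # root first

    def lca(self, taxa: Sequence[str]) -> str:
        paths = [self.path(t) for t in taxa]
        lca = self.root
        for level in zip(*paths):
            if len(set(level)) == 1:
                lca = level[0]
            else:
                break
        return lca


def lca_assign(
    query_hits: Mapping[str, Sequence[tuple[str, float]]],
    taxonomy: Taxonomy,
    min_score: float = 35.0,
    top_percent: float = 10.0,
    min_support: int = 5,
) -> dict[str, str | None]:
    """Assign each query to the LCA of its retained hits.

    Per query, hits with score >= min_score and score within
    `top_percent` percent of the best retained hit are kept; the query is
    assigned the LCA of their taxa.  After the batch pass, queries on
    taxa supported by fewer than `min_support` queries are pushed to the
    parent taxon until every assignment is supported (the root is
    exempt).  Queries with no retained hits map to None."""
    assigned: dict[str, str | None] = {}
    for qid, hits in query_hits.items():
        kept = [(t, s) for t, s in hits if s >= min_score]
        if not kept:
            assigned[qid] = None
            continue
        best = max(s for _, s in kept)
        cutoff = best * (1 - top_percent / 100.0)
        taxa = [t for t, s in kept if s >= cutoff]
        assigned[qid] = taxonomy.lca(taxa)

    while True:
        support: dict[str, int] = {}
        for t in assigned.values():
            if t is not None:
                support[t] = support.get(t, 0) + 1
        moved = False
        for qid, t in assigned.items():
            if t is not None and t != taxonomy.root and support[t] < min_support:
                assigned[qid] = taxonomy.parent[t]
                moved = True
        if not moved:
            return assigned
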