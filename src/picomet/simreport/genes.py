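"""Per-gene nucleotide similarity against a contig set.

Each panel gene is searched by local nucleotide alignment against every
contig; the best contig above the score threshold is reported with its
percent identity over the aligned region, absent genes are flagged
not-found.  The threshold is a raw alignment score (the package's
internal search computes no E-values).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from picomet.align import align_pair, dna_local_aligner


@dataclass(frozen=True)
class GeneResult:
    gene_id: str
    found: bool
    contig_id: str | None = None
    pct_identity: float | None = None
    aligned_len: int | None = None
    score: float | None = None


@dataclass
class GenePanelResult:
    genes: list[GeneResult] = field(default_factory=list)

    @property
    def n_found(self) -> int:
        return sum(1 for g in self.genes if g.found)

    @property
    def found_fraction(self) -> float:
        return self.n_found / len(self.genes) if self.genes else float("nan")

    def mean_identity(self) -> float:
        vals = [g.pct_identity for g in self.genes if g.found]
        return sum(vals) / len(vals) if vals else float("nan")

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tfound\tcontig\tpct_identity\taligned_len\tscore\n")
            for g in self.genes:
                fh.write(
                    f"{g.gene_id}\t{int(g.found)}\t{g.contig_id or ''}"
                    f"\t{'' if g.pct_identity is None else f'{g.pct_identity:.2f}'}"
                    f"\t{g.aligned_len or ''}\t{'' if g.score is None else f'{g.score:.0f}'}\n"
                )


def gene_panel_similarity(
    genes: Mapping[str, str],
    contigs: Mapping[str, str],
    min_score: float = 100.0,
) -> GenePanelResult:
    """Best-contig nucleotide similarity for each panel gene."""
    if not genes:
        raise ValueError("empty gene panel")
    aligner = dna_local_aligner()
    result = GenePanelResult()
    for gid in sorted(genes):
        gseq = genes[gid]
        best = None
        for cid in sorted(contigs):
            stats = align_pair(contigs[cid], gseq, aligner)
            if stats.score < min_score:
                continue
            if best is None or stats.score > best[0].score:
                best = (stats, cid)
        if best is None:
            result.genes.append(GeneResult(gid, found=False))
        else:
            stats, cid = best
            result.genes.append(
                GeneResult(
                    gid,
                    found=True,
                    contig_id=cid,
                    pct_identity=stats.identity * 100.0,
                    aligned_len=stats.length,
                    score=stats.score,
                )
            )
    return result
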