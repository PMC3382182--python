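"""Filtered single-nucleotide variant calls from pileup columns.

A call is made at a column iff depth >= min_cov, some non-reference
allele is seen on >= min_alt_reads reads, and its frequency is
>= min_freq.  Multiple qualifying alleles at one column produce multiple
calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from picomet.popdiv.pileup import BASES, PileupColumn


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    position: int
    ref: str
    alt: str
    alt_count: int
    depth: int

    @property
    def frequency(self) -> float:
        return self.alt_count / self.depth


def call_variants(
    columns: Sequence[PileupColumn],
    min_cov: int = 5,
    min_alt_reads: int = 2,
    min_freq: float = 0.15,
) -> list[VariantCall]:
    calls: list[VariantCall] = []
    for col in columns:
        depth = col.depth
        if depth < min_cov:
            continue
        for allele in BASES:
            if allele == col.ref_base:
                continue
            n = col.counts[allele]
            if n >= min_alt_reads and n / depth >= min_freq:
                calls.append(VariantCall(col.chrom, col.position, col.ref_base, allele, n, depth))
    return calls


def write_variants_tsv(calls: Sequence[VariantCall], path: str) -> None:
    """VCF-like TSV (POS is 1-based)."""
    with open(path, "w") as fh:
        fh.write("CHROM\tPOS\tREF\tALT\tDP\tAD\tAF\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.position + 1}\t{c.ref}\t{c.alt}\t{c.depth}\t{c.alt_count}\t{c.frequency:.4f}\n"
            )
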