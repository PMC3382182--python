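"""Minimum-haplotype decomposition of a well-covered region.

Reads are grouped by their variant signature — the (position, allele)
changes they carry at positions that pass the variant filters.  A
non-reference haplotype is declared when at least `min_reads` reads
share at least `min_shared_positions` identical changes; reads carrying
no changes form the reference haplotype.  Reads whose group fails the
shared-change requirement are merged into the nearest declared
haplotype (Hamming distance over the variant positions the read covers;
ties go to the reference).  Frequencies are computed over informative
reads only — reads overlapping at least `min_shared_positions` variant
positions.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from picomet.popdiv.pileup import pileup
from picomet.popdiv.variants import call_variants
from picomet.refmap.mapper import ReadAlignment

Signature = frozenset[tuple[int, str]]


@dataclass
class Haplotype:
    signature: Signature  # empty for the reference haplotype
    read_ids: list[str] = field(default_factory=list)
    frequency: float = 0.0

    @property
    def is_reference(self) -> bool:
        return len(self.signature) == 0


@dataclass
class HaplotypeSet:
    region: tuple[str, int, int]
    haplotypes: list[Haplotype]
    n_informative: int

    @property
    def n_min(self) -> int:
        return len(self.haplotypes)

    def frequencies(self) -> dict[Signature, float]:
        return {h.signature: h.frequency for h in self.haplotypes}


def _read_alleles(
    aln: ReadAlignment, variant_positions: Sequence[int]
) -> dict[int, str]:
    """Alleles this read shows at the given reference positions (covered only)."""
    wanted = set(variant_positions)
    out: dict[int, str] = {}
    for rpos, base in aln.columns():
        if rpos in wanted:
            out[rpos] = base
    return out


def min_haplotypes(
    alignments: Sequence[ReadAlignment],
    sequences: Mapping[str, str],
    region: tuple[str, int, int],
    min_shared_positions: int = 2,
    min_reads: int = 2,
    min_cov: int = 5,
    min_alt_reads: int = 2,
    min_freq: float = 0.15,
) -> HaplotypeSet:
    """Minimum-genotype decomposition of `region` (chrom, start, end)."""
    chrom, start, end = region
    in_region = [
        a for a in alignments if a.chrom == chrom and a.ref_start < end and a.ref_end > start
    ]
    if not in_region:
        raise ValueError(f"region {region} is covered by no reads")
    columns = pileup(in_region, sequences, region)
    calls = call_variants(columns, min_cov=min_cov, min_alt_reads=min_alt_reads, min_freq=min_freq)
    variant_positions = sorted({c.position for c in calls})
    ref = sequences[chrom]

    informative: list[tuple[ReadAlignment, Signature, dict[int, str]]] = []
    for aln in in_region:
        alleles = _read_alleles(aln, variant_positions)
        if len(alleles) < min_shared_positions:
            continue
        sig = frozenset(
            (pos, base) for pos, base in alleles.items() if base != ref[pos]
        )
        informative.append((aln, sig, alleles))
    n_informative = len(informative)

    groups: dict[Signature, list[ReadAlignment]] = defaultdict(list)
    for aln, sig, _ in informative:
        groups[sig].append(aln)

    declared: dict[Signature, Haplotype] = {}
    leftovers: list[tuple[ReadAlignment, Signature, dict[int, str]]] = []
    if frozenset() in groups:
        declared[frozenset()] = Haplotype(frozenset(), [a.read_id for a in groups[frozenset()]])
    for sig, members in groups.items():
        if not sig:
            continue
        if len(sig) >= min_shared_positions and len(members) >= min_reads:
            declared[sig] = Haplotype(sig, [a.read_id for a in members])
        else:
            for aln, s, alleles in informative:
                if s == sig:
                    leftovers.append((aln, s, alleles))

    if not declared:
        # no group qualifies: everything collapses onto the reference
        declared[frozenset()] = Haplotype(frozenset())

    # merge unsupported reads into the nearest declared haplotype
    for aln, sig, alleles in leftovers:
        best_sig: Signature | None = None
        best_dist = None
        for hsig in declared:
            hap_alleles = dict(hsig)
            dist = 0
            for pos, base in alleles.items():
                expected = hap_alleles.get(pos, ref[pos])
                if base != expected:
                    dist += 1
            key = (dist, len(hsig) > 0)  # tie -> reference (False sorts first)
            if best_dist is None or key < best_dist:
                best_dist = key
                best_sig = hsig
        declared[best_sig].read_ids.append(aln.read_id)

    haplotypes = sorted(declared.values(), key=lambda h: (-len(h.read_ids), sorted(h.signature)))
    if n_informative:
        for h in haplotypes:
            h.frequency = len(h.read_ids) / n_informative
    return HaplotypeSet(region=region, haplotypes=haplotypes, n_informative=n_informative)


def write_haplotypes_tsv(hset: HaplotypeSet, path: str) -> None:
    chrom, start, end = hset.region
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tsignature\tn_reads\tfrequency\n")
        for h in hset.haplotypes:
            sig = ";".join(f"{p + 1}{a}" for p, a in sorted(h.signature)) or "reference"
            fh.write(f"{chrom}\t{start}\t{end}\t{sig}\t{len(h.read_ids)}\t{h.frequency:.4f}\n")
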