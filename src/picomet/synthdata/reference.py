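"""Simulation of multi-chromosome reference genomes with controlled GC structure.

Chromosomes are described by plans of (length, GC) segments so that
GC-heterogeneous layouts — standard nuclear chromosomes, a tri-partite
low-GC outlier, low-GC organelles — can be generated deterministically.
A full rRNA operon (SSU–ITS–LSU) is placed on one designated chromosome
and CDS features tile a configurable fraction of every nuclear
chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

CATEGORIES = ("nuclear-standard", "nuclear-outlier", "organelle")

# rRNA operon part lengths (sum: 5646 bp).
SSU_LEN = 1800
ITS_LEN = 546
LSU_LEN = 3300

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Feature:
    """Annotated interval on a chromosome, 0-based half-open."""

    feature_id: str
    chrom: str
    start: int
    end: int
    type: str  # CDS | rRNA-SSU | rRNA-LSU | ITS
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"feature {self.feature_id}: bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.feature_id}: bad strand {self.strand!r}")


@dataclass
class Chromosome:
    id: str
    sequence: str
    category: str = "nuclear-standard"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"chromosome {self.id}: unknown category {self.category!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s) if s else 0.0


@dataclass
class ReferenceGenome:
    """Chromosome sequences plus CDS/rRNA annotation; the coordinate frame
    for every downstream computation."""

    chromosomes: list[Chromosome]
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chromosomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate chromosome ids")
        if sum(len(c) for c in self.chromosomes) <= 0:
            raise ValueError("reference genome has zero total length")
        lengths = {c.id: len(c) for c in self.chromosomes}
        for f in self.features:
            if f.chrom not in lengths:
                raise ValueError(f"feature {f.feature_id} on unknown chromosome {f.chrom}")
            if f.end > lengths[f.chrom]:
                raise ValueError(f"feature {f.feature_id} exceeds chromosome {f.chrom}")

    # -- convenience accessors -------------------------------------------------

    def __getitem__(self, chrom_id: str) -> Chromosome:
        for c in self.chromosomes:
            if c.id == chrom_id:
                return c
        raise KeyError(chrom_id)

    @property
    def sequences(self) -> dict[str, str]:
        return {c.id: c.sequence for c in self.chromosomes}

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    def feature(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def gc_by_chromosome(self) -> dict[str, float]:
        return {c.id: c.gc for c in self.chromosomes}

    # -- serialization ---------------------------------------------------------

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for c in self.chromosomes:
                fh.write(f">{c.id} category={c.category}\n")
                for i in range(0, len(c.sequence), 80):
                    fh.write(c.sequence[i : i + 80] + "\n")

    def to_gff3(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for c in self.chromosomes:
                fh.write(f"##sequence-region {c.id} 1 {len(c)}\n")
            for f in self.features:
                gtype = {"CDS": "CDS", "rRNA-SSU": "rRNA", "rRNA-LSU": "rRNA", "ITS": "misc_RNA"}[f.type]
                attrs = f"ID={f.feature_id};subtype={f.type}"
                fh.write(
                    f"{f.chrom}\tpicomet\t{gtype}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
                )


@dataclass(frozen=True)
class ChromosomePlan:
    """Plan for one chromosome: list of (length bp, target GC) segments."""

    id: str
    segments: tuple[tuple[int, float], ...]
    category: str = "nuclear-standard"
    has_rrna_operon: bool = False

    @property
    def length(self) -> int:
        return sum(length for length, _ in self.segments)


def _random_dna(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def simulate_reference(
    plans: Sequence[ChromosomePlan],
    seed: int,
    cds_fraction: float = 0.5,
    cds_length: int = 1200,
) -> ReferenceGenome:
    """Generate a reference genome from chromosome plans.

    Each segment is i.i.d. random DNA at its target GC.  CDS features tile
    `cds_fraction` of each non-organelle chromosome in alternating strand
    orientation; on the chromosome flagged ``has_rrna_operon`` an
    SSU–ITS–LSU operon is annotated near the middle (the CDS tiling skips
    the operon interval).
    """
    if not plans:
        raise ValueError("no chromosome plans given")
    rng = np.random.default_rng(seed)
    chroms: list[Chromosome] = []
    features: list[Feature] = []
    for plan in plans:
        if plan.length < 1000:
            raise ValueError(f"chromosome {plan.id}: total length {plan.length} < 1 kbp")
        parts = []
        for length, gc in plan.segments:
            if length <= 0:
                raise ValueError(f"chromosome {plan.id}: segment with non-positive length")
            if not 0 < gc < 1:
                raise ValueError(f"chromosome {plan.id}: GC target {gc} outside (0, 1)")
            parts.append(_random_dna(length, gc, rng))
        seq = b"".join(p.tobytes() for p in parts).decode()
        chroms.append(Chromosome(plan.id, seq, plan.category))

        operon: tuple[int, int] | None = None
        if plan.has_rrna_operon:
            operon_len = SSU_LEN + ITS_LEN + LSU_LEN
            if plan.length < operon_len + 2000:
                raise ValueError(f"chromosome {plan.id}: too short for an rRNA operon")
            start = (plan.length - operon_len) // 2
            features.append(Feature("rRNA-SSU-1", plan.id, start, start + SSU_LEN, "rRNA-SSU"))
            features.append(
                Feature("ITS-1", plan.id, start + SSU_LEN, start + SSU_LEN + ITS_LEN, "ITS")
            )
            features.append(
                Feature(
                    "rRNA-LSU-1", plan.id, start + SSU_LEN + ITS_LEN, start + operon_len, "rRNA-LSU"
                )
            )
            operon = (start, start + operon_len)

        if plan.category != "organelle" and cds_fraction > 0:
            features.extend(_tile_cds(plan.id, plan.length, cds_fraction, cds_length, operon))
    return ReferenceGenome(chroms, features)


def _tile_cds(
    chrom_id: str,
    length: int,
    fraction: float,
    cds_length: int,
    skip: tuple[int, int] | None,
) -> Iterable[Feature]:
    period = max(int(cds_length / fraction), cds_length + 1)
    feats = []
    i = 0
    pos = 100
    while pos + cds_length < length:
        if skip is None or not (pos < skip[1] and pos + cds_length > skip[0]):
            strand = "+" if i % 2 == 0 else "-"
            feats.append(Feature(f"{chrom_id}.cds{i:04d}", chrom_id, pos, pos + cds_length, "CDS", strand))
            i += 1
        pos += period
    return feats


def measured_gc(sequence: str, start: int = 0, end: int | None = None) -> float:
    """GC fraction of sequence[start:end]."""
    s = sequence[start:end]
    if not s:
        raise ValueError("empty interval")
    return (s.count("G") + s.count("C")) / len(s)
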