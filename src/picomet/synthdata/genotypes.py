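"""Planting of coexisting genotypes: SNPs and rRNA intron presence/absence.

Genotypes are full genome copies derived from a reference by (a) random
substitutions at a per-base rate and (b) insertion of intron sequences
into designated rRNA features.  The intron sequence for a given feature
is derived from the community seed alone, so two genotypes that both
carry "the" SSU intron carry the identical sequence — as real genotype
mixtures do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from picomet.synthdata.reference import ReferenceGenome

_ALT = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


@dataclass(frozen=True)
class IntronEdit:
    """Insert (present=True) an intron of `length` bp into feature `feature_id`.

    The insertion point sits `offset_from_end` bases before the feature end
    (introns near the end of rRNA genes).  present=False is a no-op and
    exists so genotype specs can state the absence explicitly.
    """

    feature_id: str
    present: bool
    length: int
    offset_from_end: int = 30


@dataclass(frozen=True)
class GenotypeSpec:
    label: str
    abundance: float
    snp_rate: float = 0.0
    intron_edits: tuple[IntronEdit, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.abundance <= 1:
            raise ValueError(f"genotype {self.label}: abundance {self.abundance} outside (0, 1]")
        if not 0 <= self.snp_rate <= 0.2:
            raise ValueError(f"genotype {self.label}: snp_rate {self.snp_rate} outside [0, 0.2]")


@dataclass(frozen=True)
class PlantedVariant:
    """One planted substitution, in reference coordinates."""

    genotype: str
    chrom: str
    position: int
    ref: str
    alt: str


@dataclass
class GenotypeGenome:
    label: str
    abundance: float
    chromosomes: dict[str, str]
    categories: dict[str, str]
    # ref-coordinate insertion point and sequence for each planted intron
    introns: dict[str, tuple[str, int, str]] = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def gc(self) -> float:
        n = sum(len(s) for s in self.chromosomes.values())
        gc = sum(s.count("G") + s.count("C") for s in self.chromosomes.values())
        return gc / n


def intron_sequence(seed: int, feature_id: str, length: int) -> str:
    """Deterministic intron sequence shared by all genotypes of a community."""
    sub = np.random.default_rng([seed, abs(hash(feature_id)) % (2**31), length])
    return "".join("ACGT"[i] for i in sub.integers(0, 4, size=length))


def plant_genotypes(
    ref: ReferenceGenome,
    specs: list[GenotypeSpec],
    seed: int,
) -> tuple[list[GenotypeGenome], list[PlantedVariant]]:
    """Derive genotype genomes from `ref` and return them with SNP truth.

    Abundances must sum to 1 (±1e-9).  SNP positions/alleles are drawn per
    genotype; intron insertions shift downstream coordinates but truth is
    recorded in reference coordinates.
    """
    total = sum(s.abundance for s in specs)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"genotype abundances sum to {total}, expected 1")
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate genotype labels")

    rng = np.random.default_rng(seed)
    categories = {c.id: c.category for c in ref.chromosomes}
    genomes: list[GenotypeGenome] = []
    truth: list[PlantedVariant] = []
    for spec in specs:
        chrom_seqs: dict[str, str] = {}
        introns: dict[str, tuple[str, int, str]] = {}
        # SNPs first (reference coordinates), then insertions.
        for chrom in ref.chromosomes:
            seq = np.frombuffer(chrom.sequence.encode(), dtype=np.uint8).copy()
            if spec.snp_rate > 0:
                n_sites = rng.binomial(len(seq), spec.snp_rate)
                positions = np.sort(
                    rng.choice(len(seq), size=n_sites, replace=False)
                )
                for pos in positions:
                    refbase = chr(seq[pos])
                    alt = _ALT[refbase][rng.integers(0, 3)]
                    seq[pos] = ord(alt)
                    truth.append(PlantedVariant(spec.label, chrom.id, int(pos), refbase, alt))
            chrom_seqs[chrom.id] = seq.tobytes().decode()

        for edit in spec.intron_edits:
            try:
                feat = ref.feature(edit.feature_id)
            except KeyError:
                raise ValueError(
                    f"genotype {spec.label}: intron edit targets missing feature {edit.feature_id!r}"
                ) from None
            if not feat.type.startswith("rRNA"):
                raise ValueError(
                    f"genotype {spec.label}: intron edit targets non-rRNA feature {edit.feature_id!r}"
                )
            if not edit.present:
                continue
            point = feat.end - edit.offset_from_end
            iseq = intron_sequence(seed, edit.feature_id, edit.length)
            introns[edit.feature_id] = (feat.chrom, point, iseq)

        # apply collected insertions right-to-left so earlier points stay valid
        for feature_id, (chrom_id, point, iseq) in sorted(
            introns.items(), key=lambda kv: -kv[1][1]
        ):
            s = chrom_seqs[chrom_id]
            chrom_seqs[chrom_id] = s[:point] + iseq + s[point:]

        genomes.append(
            GenotypeGenome(spec.label, spec.abundance, chrom_seqs, dict(categories), introns)
        )
    return genomes, truth


def reference_as_genotype(ref: ReferenceGenome, label: str = "reference", abundance: float = 1.0) -> GenotypeGenome:
    """Wrap a reference genome as a single genotype for read simulation."""
    return GenotypeGenome(
        label,
        abundance,
        {c.id: c.sequence for c in ref.chromosomes},
        {c.id: c.category for c in ref.chromosomes},
    )
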