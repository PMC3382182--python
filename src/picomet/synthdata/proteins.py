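"""Synthetic ortholog protein families over a genus/class taxonomy.

Each family descends from a random ancestor protein; genus ancestors
diverge from the family root at the class rate and genomes diverge from
their genus ancestor at the genus rate, so within-genus identity exceeds
within-class identity on average.  Families may be restricted to a
subset of genomes (genome-specific families exercise the classifier's
default-threshold path).  A back-translation helper turns a genome's
protein complement into a DNA genome for fragment-classification
benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"

# one codon per amino acid (back-translation); stop codon terminates genes
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


@dataclass(frozen=True)
class TaxonPlan:
    genome: str
    genus: str
    class_: str


@dataclass(frozen=True)
class DivergencePlan:
    genus: float = 0.10
    class_: float = 0.40

    def __post_init__(self) -> None:
        if not 0 <= self.genus <= self.class_ <= 1:
            raise ValueError("need 0 <= genus divergence <= class divergence <= 1")


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    genome: str
    genus: str
    class_: str
    sequence: str
    group: str


@dataclass
class ProteinFamilySet:
    proteins: list[ProteinRecord]
    # group id -> list of protein ids
    groups: dict[str, list[str]]
    taxa: list[TaxonPlan]

    def by_genome(self, genome: str) -> list[ProteinRecord]:
        return [p for p in self.proteins if p.genome == genome]

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for p in self.proteins:
                fh.write(f">{p.id}\n{p.sequence}\n")

    def to_taxonomy_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("genome\tgenus\tclass\n")
            for t in self.taxa:
                fh.write(f"{t.genome}\t{t.genus}\t{t.class_}\n")

    def to_groups_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("group\tprotein\n")
            for g, members in self.groups.items():
                for m in members:
                    fh.write(f"{g}\t{m}\n")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    n_sub = rng.binomial(len(arr), rate)
    for pos in rng.choice(len(arr), size=n_sub, replace=False):
        old = arr[pos]
        choices = AA.replace(old, "")
        arr[pos] = choices[rng.integers(0, len(choices))]
    return "".join(arr)


def simulate_protein_families(
    n_families: int,
    taxa: Sequence[TaxonPlan],
    divergence: DivergencePlan,
    seed: int,
    specific_fraction: float = 0.1,
    presence: Sequence[Sequence[str]] | None = None,
    length_range: tuple[int, int] = (90, 220),
) -> ProteinFamilySet:
    """Generate `n_families` ortholog families across `taxa`.

    `presence`, when given, lists for each family the genomes carrying it
    (overriding `specific_fraction`); otherwise a leading
    ``specific_fraction`` share of families is assigned to exactly one
    genome in rotation and the rest are universal.
    """
    if len({t.genome for t in taxa}) < 2:
        raise ValueError("need at least 2 genomes")
    if len({t.genus for t in taxa}) < 2:
        raise ValueError("need at least 2 genera")
    if presence is not None and len(presence) != n_families:
        raise ValueError("presence list length must equal n_families")
    rng = np.random.default_rng(seed)
    genomes = [t.genome for t in taxa]
    by_genome = {t.genome: t for t in taxa}
    genera = sorted({t.genus for t in taxa})

    proteins: list[ProteinRecord] = []
    groups: dict[str, list[str]] = {}
    n_specific = int(round(specific_fraction * n_families)) if presence is None else 0
    for fam in range(n_families):
        gid = f"fam{fam:04d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        root = "".join(AA[i] for i in rng.integers(0, len(AA), size=length))
        # genus ancestors diverge from root at half the class rate each, so
        # cross-genus pairs differ at ~class rate
        genus_anc = {g: _mutate(root, divergence.class_ / 2, rng) for g in genera}
        if presence is not None:
            members = list(presence[fam])
        elif fam < n_specific:
            members = [genomes[fam % len(genomes)]]
        else:
            members = list(genomes)
        ids = []
        for genome in members:
            t = by_genome[genome]
            seq = _mutate(genus_anc[t.genus], divergence.genus / 2, rng)
            pid = f"{genome}|{gid}"
            proteins.append(ProteinRecord(pid, genome, t.genus, t.class_, seq, gid))
            ids.append(pid)
        groups[gid] = ids
    return ProteinFamilySet(proteins, groups, list(taxa))


def back_translate(protein: str) -> str:
    return "".join(_CODON[a] for a in protein) + "TAA"


def synthesize_genome(
    families: ProteinFamilySet,
    genome: str,
    seed: int,
    spacer_len: int = 120,
    spacer_gc: float = 0.45,
) -> tuple[str, list[tuple[str, int, int]]]:
    """Back-translate one genome's proteins into a DNA genome.

    Genes are separated by random intergenic spacers.  Returns the
    sequence and a (protein id, start, end) gene map.
    """
    rng = np.random.default_rng([seed, 0x9E3779B9])
    parts: list[str] = []
    gene_map: list[tuple[str, int, int]] = []
    pos = 0
    p = np.array([(1 - spacer_gc) / 2, spacer_gc / 2, spacer_gc / 2, (1 - spacer_gc) / 2])
    for rec in families.by_genome(genome):
        spacer = "".join("ACGT"[i] for i in rng.choice(4, size=spacer_len, p=p))
        parts.append(spacer)
        pos += spacer_len
        gene = back_translate(rec.sequence)
        gene_map.append((rec.id, pos, pos + len(gene)))
        parts.append(gene)
        pos += len(gene)
    if not parts:
        raise ValueError(f"genome {genome!r} has no proteins")
    return "".join(parts), gene_map
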