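"""Reference protein database with taxonomy labels and ortholog groups."""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from Bio import SeqIO


@dataclass(frozen=True)
class Protein:
    id: str
    genome: str
    genus: str
    class_: str
    sequence: str


@dataclass
class ProteinDB:
    proteins: dict[str, Protein] = field(default_factory=dict)
    groups: dict[str, list[str]] = field(default_factory=dict)  # group id -> protein ids

    def __post_init__(self) -> None:
        for gid, members in self.groups.items():
            for pid in members:
                if pid not in self.proteins:
                    raise ValueError(f"group {gid} references unknown protein {pid}")

    def __len__(self) -> int:
        return len(self.proteins)

    def group_of(self, protein_id: str) -> str | None:
        for gid, members in self.groups.items():
            if protein_id in members:
                return gid
        return None

    @property
    def group_index(self) -> dict[str, str]:
        idx = {}
        for gid, members in self.groups.items():
            for pid in members:
                idx[pid] = gid
        return idx

    def genomes(self) -> list[str]:
        return sorted({p.genome for p in self.proteins.values()})

    def without_genome(self, genome: str) -> "ProteinDB":
        """Copy of the database with one genome's proteins removed
        (leave-one-out validation)."""
        keep = {pid: p for pid, p in self.proteins.items() if p.genome != genome}
        groups = {}
        for gid, members in self.groups.items():
            kept = [pid for pid in members if pid in keep]
            if kept:
                groups[gid] = kept
        return ProteinDB(keep, groups)

    @classmethod
    def from_family_set(cls, families) -> "ProteinDB":
        """Build from a synthdata ProteinFamilySet."""
        proteins = {
            p.id: Protein(p.id, p.genome, p.genus, p.class_, p.sequence)
            for p in families.proteins
        }
        return cls(proteins, {g: list(m) for g, m in families.groups.items()})

    @classmethod
    def load(cls, fasta_path: str, taxonomy_tsv: str, groups_tsv: str | None = None) -> "ProteinDB":
        """Load from protein FASTA (ids '<genome>|<rest>') + taxonomy TSV
        (genome, genus, class) + optional ortholog-groups TSV (group, protein)."""
        taxonomy: dict[str, tuple[str, str]] = {}
        with open(taxonomy_tsv) as fh:
            header = fh.readline()
            for line in fh:
                genome, genus, class_ = line.rstrip("\n").split("\t")
                taxonomy[genome] = (genus, class_)
        proteins: dict[str, Protein] = {}
        for rec in SeqIO.parse(fasta_path, "fasta"):
            genome = rec.id.split("|")[0]
            if genome not in taxonomy:
                raise ValueError(f"protein {rec.id}: genome {genome!r} missing from taxonomy")
            genus, class_ = taxonomy[genome]
            proteins[rec.id] = Protein(rec.id, genome, genus, class_, str(rec.seq))
        groups: dict[str, list[str]] = defaultdict(list)
        if groups_tsv:
            with open(groups_tsv) as fh:
                fh.readline()
                for line in fh:
                    gid, pid = line.rstrip("\n").split("\t")
                    groups[gid].append(pid)
        return cls(proteins, dict(groups))
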