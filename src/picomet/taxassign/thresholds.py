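"""Per-protein minimum identity / minimum alignment-length thresholds.

For every protein with orthologs, the genus-rank row is the minimum
identity and minimum alignment length observed over end-gap-free global
alignments against its within-genus ortholog partners; the class-rank
row is the minimum over all within-class partners (a superset, so the
class identity floor never exceeds the genus one).  Proteins whose group
spans a single genome are flagged SPECIFIC and fall back to the default
(80% identity over 50 aa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from picomet.align import align_pair, protein_global_aligner
from picomet.taxassign.db import ProteinDB

DEFAULT_IDENTITY = 0.80
DEFAULT_LENGTH = 50


@dataclass(frozen=True)
class ThresholdRow:
    i_min_genus: float | None
    l_min_genus: int | None
    i_min_class: float | None
    l_min_class: int | None
    specific: bool

    def __post_init__(self) -> None:
        if (
            self.i_min_genus is not None
            and self.i_min_class is not None
            and self.i_min_class > self.i_min_genus + 1e-12
        ):
            raise ValueError("class identity floor exceeds genus floor")


@dataclass
class ThresholdMatrix:
    rows: dict[str, ThresholdRow] = field(default_factory=dict)
    default_identity: float = DEFAULT_IDENTITY
    default_length: int = DEFAULT_LENGTH

    def __getitem__(self, protein_id: str) -> ThresholdRow:
        return self.rows[protein_id]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.rows

    def to_tsv(self, path: str) -> None:
        def fmt(v):
            return "" if v is None else (f"{v:.4f}" if isinstance(v, float) else str(v))

        with open(path, "w") as fh:
            fh.write("protein\ti_min_genus\tl_min_genus\ti_min_class\tl_min_class\tspecific\n")
            for pid, r in sorted(self.rows.items()):
                fh.write(
                    f"{pid}\t{fmt(r.i_min_genus)}\t{fmt(r.l_min_genus)}"
                    f"\t{fmt(r.i_min_class)}\t{fmt(r.l_min_class)}\t{int(r.specific)}\n"
                )


def build_threshold_matrix(db: ProteinDB) -> ThresholdMatrix:
    """Pre-compute the per-protein (I_min, L_min) threshold matrix."""
    if not db.proteins:
        raise ValueError("empty protein database")
    aligner = protein_global_aligner()
    matrix = ThresholdMatrix()
    group_index = db.group_index
    for pid, prot in db.proteins.items():
        gid = group_index.get(pid)
        partners = (
            [db.proteins[m] for m in db.groups[gid] if m != pid and db.proteins[m].genome != prot.genome]
            if gid
            else []
        )
        if not partners or len({p.genome for p in partners} | {prot.genome}) < 2:
            matrix.rows[pid] = ThresholdRow(None, None, None, None, specific=True)
            continue
        genus_pairs = [p for p in partners if p.genus == prot.genus and p.class_ == prot.class_]
        class_pairs = [p for p in partners if p.class_ == prot.class_]
        ig = lg = ic = lc = None
        if class_pairs:
            stats = [align_pair(prot.sequence, p.sequence, aligner) for p in class_pairs]
            ic = min(s.identity for s in stats)
            lc = min(s.length for s in stats)
            if genus_pairs:
                gstats = [align_pair(prot.sequence, p.sequence, aligner) for p in genus_pairs]
                ig = min(s.identity for s in gstats)
                lg = min(s.length for s in gstats)
        if ic is None:
            matrix.rows[pid] = ThresholdRow(None, None, None, None, specific=True)
        else:
            matrix.rows[pid] = ThresholdRow(ig, lg, ic, lc, specific=False)
    return matrix
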