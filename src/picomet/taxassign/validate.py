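"""Leave-one-out false-positive validation of the threshold classifier.

Random DNA fragments of a held-out genome are classified against a
database and threshold matrix built without that genome.  The raw
best-hit rate counts every fragment whose best merged subject belongs to
a genus other than the held-out genome's; the filtered rate counts only
fragments whose final genus-rank claim (genus level or the best-hit
default, which is a genus claim) names a wrong genus.  Class-level
assignments are never counted as false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from picomet.refmap.mapper import revcomp
from picomet.taxassign.classify import classify_query
from picomet.taxassign.db import ProteinDB
from picomet.taxassign.merge import merge_by_subject
from picomet.taxassign.search import SeedIndex, translated_search
from picomet.taxassign.thresholds import ThresholdMatrix, build_threshold_matrix


@dataclass
class FalsePositiveResult:
    fragment_len: int
    n_fragments: int
    fp_bbh: float
    fp_filtered: float
    n_bbh_wrong: int
    n_filtered_wrong: int


@dataclass
class ValidationReport:
    genome: str
    true_genus: str
    by_length: list[FalsePositiveResult] = field(default_factory=list)

    def result(self, fragment_len: int) -> FalsePositiveResult:
        for r in self.by_length:
            if r.fragment_len == fragment_len:
                return r
        raise KeyError(fragment_len)


def validate_false_positives(
    db: ProteinDB,
    matrix: ThresholdMatrix,
    genome_sequence: str,
    true_genus: str,
    n_fragments: int,
    seed: int,
    fragment_lens: Sequence[int] = (500,),
    min_score: float = 35.0,
    genome_label: str = "held-out",
) -> ValidationReport:
    """Classify random fragments of `genome_sequence` and count wrong-genus calls."""
    for flen in fragment_lens:
        if flen > len(genome_sequence):
            raise ValueError(f"fragment length {flen} exceeds genome length {len(genome_sequence)}")
    rng = np.random.default_rng(seed)
    index = SeedIndex(db)
    report = ValidationReport(genome=genome_label, true_genus=true_genus)
    for flen in fragment_lens:
        n_bbh_wrong = 0
        n_filtered_wrong = 0
        for _ in range(n_fragments):
            start = int(rng.integers(0, len(genome_sequence) - flen + 1))
            frag = genome_sequence[start : start + flen]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            hits = translated_search("frag", frag, db, min_score=min_score, seed_index=index)
            merged = merge_by_subject(hits)
            if merged:
                best = min(merged, key=lambda m: (-m.score, m.subject_id))
                if db.proteins[best.subject_id].genus != true_genus:
                    n_bbh_wrong += 1
            a = classify_query("frag", frag, db, matrix, min_score=min_score, seed_index=index, hits=hits)
            if a.level in ("genus", "bbh-default") and a.taxon != true_genus:
                n_filtered_wrong += 1
        report.by_length.append(
            FalsePositiveResult(
                fragment_len=flen,
                n_fragments=n_fragments,
                fp_bbh=n_bbh_wrong / n_fragments,
                fp_filtered=n_filtered_wrong / n_fragments,
                n_bbh_wrong=n_bbh_wrong,
                n_filtered_wrong=n_filtered_wrong,
            )
        )
    return report


def leave_one_out(
    db: ProteinDB,
    held_out_genome: str,
    genome_sequence: str,
    n_fragments: int,
    seed: int,
    fragment_lens: Sequence[int] = (500,),
    min_score: float = 35.0,
) -> ValidationReport:
    """Remove one genome from the database, rebuild the matrix, and run
    the false-positive validation on that genome's DNA."""
    genera = {p.genome: p.genus for p in db.proteins.values()}
    if held_out_genome not in genera:
        raise ValueError(f"genome {held_out_genome!r} not in database")
    true_genus = genera[held_out_genome]
    reduced = db.without_genome(held_out_genome)
    matrix = build_threshold_matrix(reduced)
    report = validate_false_positives(
        reduced,
        matrix,
        genome_sequence,
        true_genus,
        n_fragments,
        seed,
        fragment_lens=fragment_lens,
        min_score=min_score,
        genome_label=held_out_genome,
    )
    return report
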