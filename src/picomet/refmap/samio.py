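"""Plain-text SAM import/export for read alignments (1-based in SAM,
0-based half-open internally)."""

from __future__ import annotations

from typing import Mapping, Sequence

import pysam

from picomet.refmap.mapper import ReadAlignment


def write_sam(
    alignments: Sequence[ReadAlignment], sequences: Mapping[str, str], path: str
) -> None:
    chrom_ids = sorted(sequences)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for cid in chrom_ids:
            fh.write(f"@SQ\tSN:{cid}\tLN:{len(sequences[cid])}\n")
        fh.write("@PG\tID:picomet\tPN:picomet\n")
        for aln in alignments:
            flag = 16 if aln.strand == "-" else 0
            cigar = "".join(f"{n}{op}" for op, n in aln.cigar)
            nm = aln.mismatches
            fh.write(
                f"{aln.read_id}\t{flag}\t{aln.chrom}\t{aln.ref_start + 1}\t60\t{cigar}"
                f"\t*\t0\t0\t{aln.seq}\t*\tNM:i:{nm}\tAS:i:{int(aln.score)}\n"
            )


def read_sam(path: str) -> list[ReadAlignment]:
    """Import mapped records from a SAM file.

    Identity and mismatch counts are taken from the NM tag when present;
    otherwise mismatches default to gap columns only (sequence-level
    mismatches cannot be recovered without the reference)."""
    out: list[ReadAlignment] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped or rec.cigartuples is None:
                continue
            cigar: list[tuple[str, int]] = []
            columns = 0
            for op, n in rec.cigartuples:
                letter = "MIDNSHP=X"[op]
                if letter in "=X":
                    letter = "M"
                if letter in "MID":
                    columns += n
                if letter in "MIDS":
                    cigar.append((letter, n))
            nm = rec.get_tag("NM") if rec.has_tag("NM") else sum(
                n for op, n in cigar if op in "ID"
            )
            score = float(rec.get_tag("AS")) if rec.has_tag("AS") else 0.0
            out.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    ref_start=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    cigar=cigar,
                    seq=rec.query_sequence or "",
                    mismatches=int(nm),
                    score=score,
                    identity=1.0 - int(nm) / columns if columns else 0.0,
                    aligned_len=columns,
                )
            )
    return out
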