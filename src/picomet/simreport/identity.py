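"""Identity reports over depth-masked three-way alignments.

Per chromosome and in total: alignment length, percent of columns where
all three sequences agree, pairwise identical-site percentages, and
CDS / non-CDS splits.  A column counts as CDS when it lies inside any
CDS feature on either strand.  Totals are length-weighted recomputations
from the per-chromosome rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from picomet.simreport.mask import MaskedAlignment
from picomet.synthdata.reference import Feature


@dataclass(frozen=True)
class IdentityRow:
    chrom: str
    length: int
    length_cds: int
    length_noncds: int
    pct_three_way: float
    pct_three_way_cds: float
    pct_three_way_noncds: float
    pct_ref_a: float
    pct_ref_b: float
    pct_a_b: float


@dataclass
class IdentityReport:
    rows: list[IdentityRow]
    total: IdentityRow

    def to_tsv(self, path: str) -> None:
        cols = (
            "chrom\tlength\tlength_cds\tlength_noncds\tpct_three_way\tpct_three_way_cds"
            "\tpct_three_way_noncds\tpct_ref_a\tpct_ref_b\tpct_a_b\n"
        )
        with open(path, "w") as fh:
            fh.write(cols)
            for r in list(self.rows) + [self.total]:
                fh.write(
                    f"{r.chrom}\t{r.length}\t{r.length_cds}\t{r.length_noncds}"
                    f"\t{r.pct_three_way:.2f}\t{r.pct_three_way_cds:.2f}\t{r.pct_three_way_noncds:.2f}"
                    f"\t{r.pct_ref_a:.2f}\t{r.pct_ref_b:.2f}\t{r.pct_a_b:.2f}\n"
                )


def _pct(mask: np.ndarray, sel: np.ndarray | None = None) -> float:
    v = mask if sel is None else mask[sel]
    return float(v.mean()) * 100.0 if len(v) else float("nan")


def identity_row(masked: MaskedAlignment, features: Sequence[Feature]) -> IdentityRow:
    n = len(masked)
    if n == 0:
        raise ValueError(f"{masked.chrom}: masked alignment is empty")
    ref = np.frombuffer(masked.ref.encode(), dtype=np.uint8)
    a = np.frombuffer(masked.cons_a.encode(), dtype=np.uint8)
    b = np.frombuffer(masked.cons_b.encode(), dtype=np.uint8)
    eq_ra = ref == a
    eq_rb = ref == b
    eq_ab = a == b
    three = eq_ra & eq_rb
    is_cds = np.zeros(n, dtype=bool)
    pos = masked.positions
    for f in features:
        if f.type == "CDS" and f.chrom == masked.chrom:
            is_cds |= (pos >= f.start) & (pos < f.end)
    return IdentityRow(
        chrom=masked.chrom,
        length=n,
        length_cds=int(is_cds.sum()),
        length_noncds=int((~is_cds).sum()),
        pct_three_way=_pct(three),
        pct_three_way_cds=_pct(three, is_cds),
        pct_three_way_noncds=_pct(three, ~is_cds),
        pct_ref_a=_pct(eq_ra),
        pct_ref_b=_pct(eq_rb),
        pct_a_b=_pct(eq_ab),
    )


def weighted_total(rows: Sequence[IdentityRow], label: str = "total") -> IdentityRow:
    """Length-weighted totals recomputed from per-chromosome rows."""

    def wmean(vals, weights):
        w = np.array(weights, dtype=float)
        v = np.array(vals, dtype=float)
        ok = w > 0
        return float(np.average(v[ok], weights=w[ok])) if ok.any() else float("nan")

    return IdentityRow(
        chrom=label,
        length=sum(r.length for r in rows),
        length_cds=sum(r.length_cds for r in rows),
        length_noncds=sum(r.length_noncds for r in rows),
        pct_three_way=wmean([r.pct_three_way for r in rows], [r.length for r in rows]),
        pct_three_way_cds=wmean([r.pct_three_way_cds for r in rows], [r.length_cds for r in rows]),
        pct_three_way_noncds=wmean(
            [r.pct_three_way_noncds for r in rows], [r.length_noncds for r in rows]
        ),
        pct_ref_a=wmean([r.pct_ref_a for r in rows], [r.length for r in rows]),
        pct_ref_b=wmean([r.pct_ref_b for r in rows], [r.length for r in rows]),
        pct_a_b=wmean([r.pct_a_b for r in rows], [r.length for r in rows]),
    )


def identity_report(
    masked_alignments: Sequence[MaskedAlignment], features: Sequence[Feature]
) -> IdentityReport:
    if not masked_alignments:
        raise ValueError("no masked alignments given")
    rows = [identity_row(m, features) for m in masked_alignments]
    return IdentityReport(rows=rows, total=weighted_total(rows))
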