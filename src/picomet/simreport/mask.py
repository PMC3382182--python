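"""Column-wise three-way alignment and depth masking.

Consensuses are reference-projected (same length as the reference by
construction), so the three-way alignment is column-wise exact and no
multiple aligner is needed.  Masking retains a reference column iff BOTH
samples reach `min_depth` there; retained regions are reported as
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ThreeWayAlignment:
    chrom: str
    ref: str
    cons_a: str
    cons_b: str

    def __post_init__(self) -> None:
        if not len(self.ref) == len(self.cons_a) == len(self.cons_b):
            raise ValueError(
                f"{self.chrom}: sequences must share the reference coordinate frame "
                f"({len(self.ref)}/{len(self.cons_a)}/{len(self.cons_b)})"
            )

    def __len__(self) -> int:
        return len(self.ref)


def anchored_align(chrom: str, ref: str, cons_a: str, cons_b: str) -> ThreeWayAlignment:
    """Column-wise three-way alignment of reference-projected consensuses."""
    return ThreeWayAlignment(chrom, ref, cons_a, cons_b)


@dataclass
class MaskedAlignment:
    chrom: str
    positions: np.ndarray  # retained reference positions, ascending
    ref: str  # columns at retained positions only
    cons_a: str
    cons_b: str
    intervals: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.positions)


def _intervals(positions: np.ndarray) -> list[tuple[int, int]]:
    if len(positions) == 0:
        return []
    breaks = np.nonzero(np.diff(positions) > 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(positions) - 1]))
    return [(int(positions[s]), int(positions[e]) + 1) for s, e in zip(starts, ends)]


def mask_low_coverage(
    alignment: ThreeWayAlignment,
    depth_a: np.ndarray,
    depth_b: np.ndarray,
    min_depth: int = 10,
) -> MaskedAlignment:
    """Discard every column where either sample is below `min_depth`."""
    n = len(alignment)
    if len(depth_a) != n or len(depth_b) != n:
        raise ValueError(f"{alignment.chrom}: depth arrays do not match alignment length")
    keep = (np.asarray(depth_a) >= min_depth) & (np.asarray(depth_b) >= min_depth)
    positions = np.nonzero(keep)[0]
    pick = lambda s: "".join(s[i] for i in positions)  # noqa: E731
    return MaskedAlignment(
        chrom=alignment.chrom,
        positions=positions,
        ref=pick(alignment.ref),
        cons_a=pick(alignment.cons_a),
        cons_b=pick(alignment.cons_b),
        intervals=_intervals(positions),
    )
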