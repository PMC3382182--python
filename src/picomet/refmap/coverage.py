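"""Per-base coverage, consensus calling and window tracks.

Definitions: coverage fraction is the share of reference bases covered
by at least one read; coverage depth is the mean number of reads
covering each base; the identical-sites percentage compares the
read consensus to the reference over read-covered columns only.
Consensus ties and zero-coverage columns resolve to the reference base
(uncovered columns are flagged), keeping coordinates stable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from picomet.refmap.mapper import ReadAlignment

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4}
_IDX_BASE = "ACGT-"


def base_counts(
    alignments: Sequence[ReadAlignment], sequences: Mapping[str, str]
) -> dict[str, np.ndarray]:
    """Per-chromosome (5, L) arrays of A/C/G/T/gap counts per reference column."""
    counts = {cid: np.zeros((5, len(seq)), dtype=np.int32) for cid, seq in sequences.items()}
    for aln in alignments:
        if aln.chrom not in counts:
            raise KeyError(f"alignment on unknown chromosome {aln.chrom}")
        arr = counts[aln.chrom]
        for rpos, base in aln.columns():
            idx = _BASE_IDX.get(base)
            if idx is not None:
                arr[idx, rpos] += 1
    return counts


@dataclass
class ChromosomeCoverage:
    chrom: str
    length: int
    n_reads: int
    depth: np.ndarray  # reads covering each base (A/C/G/T/gap channels all count)
    covered_bp: int
    coverage_fraction: float
    coverage_depth: float
    identical_sites_pct: float


@dataclass
class CoverageProfile:
    chromosomes: dict[str, ChromosomeCoverage]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes.values())

    @property
    def covered_bp(self) -> int:
        return sum(c.covered_bp for c in self.chromosomes.values())

    @property
    def coverage_fraction(self) -> float:
        return self.covered_bp / self.total_length

    @property
    def coverage_depth(self) -> float:
        return sum(c.depth.sum() for c in self.chromosomes.values()) / self.total_length


def coverage_profile(
    alignments: Sequence[ReadAlignment], sequences: Mapping[str, str]
) -> CoverageProfile:
    """Compute per-chromosome coverage statistics from alignments."""
    counts = base_counts(alignments, sequences)
    reads_per_chrom: dict[str, int] = {cid: 0 for cid in sequences}
    for aln in alignments:
        reads_per_chrom[aln.chrom] += 1
    out: dict[str, ChromosomeCoverage] = {}
    for cid, seq in sequences.items():
        arr = counts[cid]
        depth = arr.sum(axis=0)
        covered = depth > 0
        covered_bp = int(covered.sum())
        cons, _ = _consensus_from_counts(arr, seq)
        refarr = np.frombuffer(seq.encode(), dtype=np.uint8)
        consarr = np.frombuffer(cons.encode(), dtype=np.uint8)
        if covered_bp:
            ident = float((consarr[covered] == refarr[covered]).mean()) * 100.0
        else:
            ident = float("nan")
        out[cid] = ChromosomeCoverage(
            chrom=cid,
            length=len(seq),
            n_reads=reads_per_chrom[cid],
            depth=depth,
            covered_bp=covered_bp,
            coverage_fraction=covered_bp / len(seq),
            coverage_depth=float(depth.mean()),
            identical_sites_pct=ident,
        )
    return CoverageProfile(out)


def _consensus_from_counts(arr: np.ndarray, ref_seq: str) -> tuple[str, np.ndarray]:
    depth = arr.sum(axis=0)
    covered = depth > 0
    winners = arr[:4].argmax(axis=0)  # gap channel cannot replace a base in the consensus string
    best = arr[:4].max(axis=0)
    # tie -> reference base: a column ties when the reference base count equals the max
    refarr = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
    ref_idx = np.full(len(ref_seq), 4, dtype=np.int64)
    for base, idx in list(_BASE_IDX.items())[:4]:
        ref_idx[refarr == ord(base)] = idx
    take_ref = ~covered
    in_range = ref_idx < 4
    ref_count = np.zeros(len(ref_seq), dtype=arr.dtype)
    ref_count[in_range] = arr[ref_idx[in_range], np.nonzero(in_range)[0]]
    tie_to_ref = in_range & (ref_count == best)
    cons_idx = winners.copy()
    cons_idx[tie_to_ref] = ref_idx[tie_to_ref]
    cons = np.array(list(_IDX_BASE[:4].encode()), dtype=np.uint8)[cons_idx]
    cons[take_ref] = refarr[take_ref]
    return cons.tobytes().decode(), covered


def consensus(
    alignments: Sequence[ReadAlignment], sequences: Mapping[str, str]
) -> tuple[dict[str, str], dict[str, np.ndarray]]:
    """Majority-base consensus per chromosome, projected onto reference
    coordinates, plus per-base depth arrays.

    Returns (consensus sequences, depth arrays).  Ties and uncovered
    columns take the reference base; uncovered columns can be recovered
    from the depth array."""
    counts = base_counts(alignments, sequences)
    cons: dict[str, str] = {}
    depths: dict[str, np.ndarray] = {}
    for cid, seq in sequences.items():
        arr = counts[cid]
        c, _ = _consensus_from_counts(arr, seq)
        cons[cid] = c
        depths[cid] = arr.sum(axis=0)
    return cons, depths


def window_tracks(
    depth: Mapping[str, np.ndarray],
    sequences: Mapping[str, str],
    window: int = 5000,
) -> list[dict]:
    """Non-overlapping (GC, mean depth) windows; the final partial window
    keeps its true length."""
    if window < 100:
        raise ValueError("window must be >= 100 bp")
    rows: list[dict] = []
    for cid in sorted(sequences):
        seq = sequences[cid]
        d = depth[cid]
        if len(d) != len(seq):
            raise ValueError(f"depth array length mismatch on {cid}")
        for s in range(0, len(seq), window):
            e = min(s + window, len(seq))
            sub = seq[s:e]
            rows.append(
                {
                    "chrom": cid,
                    "start": s,
                    "end": e,
                    "gc": (sub.count("G") + sub.count("C")) / len(sub),
                    "mean_depth": float(d[s:e].mean()),
                }
            )
    return rows
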