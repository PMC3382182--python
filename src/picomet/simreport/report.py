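"""Tabular run reports: read statistics, per-chromosome coverage table,
identity table, and a consistency-checked run summary."""

from __future__ import annotations

import json
import os
from typing import Mapping, Sequence

import pandas as pd

from picomet.refmap.coverage import CoverageProfile
from picomet.simreport.identity import IdentityReport
from picomet.synthdata.reads import ReadRecord


def read_stats(reads: Sequence[ReadRecord]) -> dict:
    """Read-set summary: count, total/mean/min/max length, GC."""
    if not reads:
        return {"n_reads": 0, "total_bp": 0, "mean_len": 0, "min_len": 0, "max_len": 0, "gc_pct": float("nan")}
    lengths = [len(r.sequence) for r in reads]
    total = sum(lengths)
    gc = sum(r.sequence.count("G") + r.sequence.count("C") for r in reads)
    return {
        "n_reads": len(reads),
        "total_bp": total,
        "mean_len": round(total / len(reads)),
        "min_len": min(lengths),
        "max_len": max(lengths),
        "gc_pct": round(gc / total * 100.0, 1),
    }


def coverage_table(profile: CoverageProfile, gc: Mapping[str, float]) -> pd.DataFrame:
    """Per-chromosome coverage table plus a recomputed totals row."""
    rows = []
    for cid in sorted(profile.chromosomes):
        c = profile.chromosomes[cid]
        rows.append(
            {
                "chrom": cid,
                "length_bp": c.length,
                "gc_pct": round(gc[cid] * 100.0, 2),
                "n_reads": c.n_reads,
                "covered_bp": c.covered_bp,
                "coverage_pct": round(c.coverage_fraction * 100.0, 2),
                "coverage_depth": round(c.coverage_depth, 2),
                "identical_sites_pct": round(c.identical_sites_pct, 2),
            }
        )
    df = pd.DataFrame(rows)
    total = {
        "chrom": "total",
        "length_bp": int(df["length_bp"].sum()),
        "gc_pct": float("nan"),
        "n_reads": int(df["n_reads"].sum()),
        "covered_bp": int(df["covered_bp"].sum()),
        "coverage_pct": round(df["covered_bp"].sum() / df["length_bp"].sum() * 100.0, 2),
        "coverage_depth": round(profile.coverage_depth, 2),
        "identical_sites_pct": float("nan"),
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def run_report(
    out_dir: str,
    reads: Sequence[ReadRecord] | None = None,
    n_mapped: int | None = None,
    profile: CoverageProfile | None = None,
    gc: Mapping[str, float] | None = None,
    identity: IdentityReport | None = None,
    seeds: Mapping[str, int] | None = None,
) -> dict:
    """Write available stage outputs as TSV/JSON under `out_dir`.

    Raises if a requested table lacks its upstream input (coverage table
    needs both a profile and per-chromosome GC)."""
    os.makedirs(out_dir, exist_ok=True)
    summary: dict = {"seeds": dict(seeds or {})}
    if reads is not None:
        stats = read_stats(reads)
        if n_mapped is not None:
            stats["mapped_pct"] = round(n_mapped / stats["n_reads"] * 100.0, 1) if stats["n_reads"] else 0.0
        summary["reads"] = stats
    if profile is not None:
        if gc is None:
            raise ValueError("coverage table requires per-chromosome GC (stage 'reference' output missing)")
        coverage_table(profile, gc).to_csv(os.path.join(out_dir, "coverage.tsv"), sep="\t", index=False)
        summary["coverage_fraction"] = profile.coverage_fraction
        summary["coverage_depth"] = profile.coverage_depth
    if identity is not None:
        identity.to_tsv(os.path.join(out_dir, "identity.tsv"))
        summary["pct_three_way_total"] = identity.total.pct_three_way
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
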