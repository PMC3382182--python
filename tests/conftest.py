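"""Shared fixtures: a small reference genome, genotype communities,
protein family sets, and truth-based alignment builders (so population
analytics can be tested without re-running the mapper)."""

from __future__ import annotations

import numpy as np
import pytest

from picomet.refmap.mapper import ReadAlignment, revcomp
from picomet.synthdata import (
    ChromosomePlan,
    DivergencePlan,
    GenotypeSpec,
    MdaParams,
    TaxonPlan,
    plant_genotypes,
    simulate_mda_reads,
    simulate_protein_families,
    simulate_reference,
)
from picomet.synthdata.genotypes import reference_as_genotype


@pytest.fixture(scope="session")
def small_ref():
    plans = [
        ChromosomePlan("chr1", ((30000, 0.48),), has_rrna_operon=True),
        ChromosomePlan("chr2", ((8000, 0.47), (8000, 0.39), (8000, 0.47)), category="nuclear-outlier"),
        ChromosomePlan("mito", ((6000, 0.40),), category="organelle"),
    ]
    return simulate_reference(plans, seed=101)


@pytest.fixture(scope="session")
def single_chrom_ref():
    return simulate_reference([ChromosomePlan("chr1", ((60000, 0.48),))], seed=11)


@pytest.fixture(scope="session")
def mixture_85_15(small_ref):
    """Two genotypes at 85/15 with the minor one carrying ~1% SNPs."""
    specs = [GenotypeSpec("major", 0.85, 0.0), GenotypeSpec("minor", 0.15, 0.01)]
    genomes, snp_truth = plant_genotypes(small_ref, specs, seed=7)
    return genomes, snp_truth


@pytest.fixture(scope="session")
def taxa_2x2():
    return [
        TaxonPlan("gA1", "GenusA", "ClassM"),
        TaxonPlan("gA2", "GenusA", "ClassM"),
        TaxonPlan("gB1", "GenusB", "ClassM"),
        TaxonPlan("gB2", "GenusB", "ClassM"),
    ]


@pytest.fixture(scope="session")
def family_set(taxa_2x2):
    # 30 universal families, 8 present in gA1 + GenusB only (classifier
    # traps under leave-one-out of gA1), 2 specific to gA1
    presence = [["gA1", "gA2", "gB1", "gB2"]] * 30 + [["gA1", "gB1", "gB2"]] * 8 + [["gA1"]] * 2
    return simulate_protein_families(
        40, taxa_2x2, DivergencePlan(0.10, 0.40), seed=5, presence=presence
    )


def alignments_from_truth(reads, truth, min_len: int = 1) -> list[ReadAlignment]:
    """Perfect-placement alignments straight from the generator's truth
    (valid when genotype coordinates equal reference coordinates, i.e.
    SNP-only genotypes)."""
    by_read = truth.by_read()
    out = []
    for rec in reads:
        t = by_read[rec.id]
        seq = rec.sequence if t.strand == "+" else revcomp(rec.sequence)
        n = t.end - t.start
        if n < min_len or len(seq) != n:
            continue
        out.append(
            ReadAlignment(
                read_id=rec.id,
                chrom=t.chrom,
                ref_start=t.start,
                strand=t.strand,
                cigar=[("M", n)],
                seq=seq,
                mismatches=t.errors,
                score=2.0 * n,
                identity=1.0 - t.errors / n,
                aligned_len=n,
            )
        )
    return out


def depth_from_truth(truth, lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-base depth computed from truth intervals only."""
    depth = {cid: np.zeros(n, dtype=np.int64) for cid, n in lengths.items()}
    for row in truth.rows:
        depth[row.chrom][row.start : row.end] += 1
    return depth


@pytest.fixture(scope="session")
def uniform_reads(single_chrom_ref):
    """Error-free, bias-free reads from a single reference genotype."""
    g = reference_as_genotype(single_chrom_ref)
    params = MdaParams(log_sd=0.0, gc_slope=0.0, error_rate=0.0)
    reads, truth = simulate_mda_reads([g], 2000, params, seed=3)
    return reads, truth
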