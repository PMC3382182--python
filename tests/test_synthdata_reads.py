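import numpy as np
import pytest
from scipy import stats as sps

from conftest import depth_from_truth
from picomet.refmap.stats import gc_coverage_correlation
from picomet.synthdata import (
    ChromosomePlan,
    GenotypeSpec,
    MdaParams,
    plant_genotypes,
    simulate_mda_reads,
    simulate_reference,
)
from picomet.synthdata.genotypes import reference_as_genotype
from picomet.synthdata.reads import read_fastq, write_fastq


def _window_cv(depth: np.ndarray, window: int = 10_000) -> float:
    means = [depth[s : s + window].mean() for s in range(0, len(depth) - window + 1, window)]
    return float(np.std(means) / np.mean(means))


class TestSimulateMdaReads:
    def test_zero_reads(self, single_chrom_ref):
        g = reference_as_genotype(single_chrom_ref)
        reads, truth = simulate_mda_reads([g], 0, MdaParams(), seed=1)
        assert reads == [] and len(truth) == 0

    def test_negative_reads_error(self, single_chrom_ref):
        g = reference_as_genotype(single_chrom_ref)
        with pytest.raises(ValueError):
            simulate_mda_reads([g], -1, MdaParams(), seed=1)

    def test_every_read_has_one_truth_row(self, uniform_reads):
        reads, truth = uniform_reads
        assert len(truth) == len(reads)
        assert {r.read_id for r in truth.rows} == {r.id for r in reads}

    def test_read_lengths_within_law(self, uniform_reads):
        reads, _ = uniform_reads
        lo, hi, mean, _ = MdaParams().read_length_law
        lengths = [len(r.sequence) for r in reads]
        assert min(lengths) >= lo and max(lengths) <= hi
        assert abs(np.mean(lengths) - mean) < 60

    def test_determinism(self, single_chrom_ref):
        g = reference_as_genotype(single_chrom_ref)
        r1, t1 = simulate_mda_reads([g], 200, MdaParams(), seed=5)
        r2, t2 = simulate_mda_reads([g], 200, MdaParams(), seed=5)
        assert r1 == r2 and t1.rows == t2.rows

    def test_truth_slices_match_reads_when_error_free(self, single_chrom_ref, uniform_reads):
        from picomet.refmap.mapper import revcomp

        reads, truth = uniform_reads
        seq = single_chrom_ref["chr1"].sequence
        for rec, row in list(zip(reads, truth.rows))[:100]:
            frag = seq[row.start : row.end]
            assert rec.sequence == (frag if row.strand == "+" else revcomp(frag))

    def test_depth_cv_small_without_bias(self, single_chrom_ref):
        # oracle: direct window counts; Poisson sampling at ~20x mean depth
        g = reference_as_genotype(single_chrom_ref)
        n = int(20 * 60_000 / 420)
        params = MdaParams(log_sd=0.0, gc_slope=0.0, error_rate=0.0)
        _, truth = simulate_mda_reads([g], n, params, seed=8)
        depth = depth_from_truth(truth, {"chr1": 60_000})["chr1"]
        assert _window_cv(depth) < 0.35

    def test_lognormal_bias_raises_cv(self, single_chrom_ref):
        g = reference_as_genotype(single_chrom_ref)
        n = int(20 * 60_000 / 420)
        for rep in range(5):
            _, t0 = simulate_mda_reads([g], n, MdaParams(log_sd=0.0, error_rate=0.0), seed=100 + rep)
            _, t1 = simulate_mda_reads([g], n, MdaParams(log_sd=1.2, error_rate=0.0), seed=100 + rep)
            cv0 = _window_cv(depth_from_truth(t0, {"chr1": 60_000})["chr1"])
            cv1 = _window_cv(depth_from_truth(t1, {"chr1": 60_000})["chr1"])
            assert cv1 > cv0

    def test_abundance_conservation(self, small_ref):
        specs = [GenotypeSpec("a", 0.85), GenotypeSpec("b", 0.15)]
        genomes, _ = plant_genotypes(small_ref, specs, seed=1)
        n = 4000
        _, truth = simulate_mda_reads(genomes, n, MdaParams(log_sd=0.5), seed=2)
        frac = truth.genome_fractions()
        sigma = np.sqrt(0.85 * 0.15 / n)
        assert abs(frac["a"] - 0.85) < 3 * sigma
        assert abs(frac["b"] - 0.15) < 3 * sigma

    def test_abundances_must_sum_to_one(self, small_ref):
        genomes, _ = plant_genotypes(small_ref, [GenotypeSpec("a", 1.0)], seed=1)
        genomes[0].abundance = 0.7
        with pytest.raises(ValueError, match="sum"):
            simulate_mda_reads(genomes, 10, MdaParams(), seed=1)

    def test_error_rate_recorded_in_truth(self, single_chrom_ref):
        g = reference_as_genotype(single_chrom_ref)
        reads, truth = simulate_mda_reads([g], 500, MdaParams(error_rate=0.02, log_sd=0.0), seed=3)
        total_errors = sum(r.errors for r in truth.rows)
        total_bases = sum(len(r.sequence) for r in reads)
        rate = total_errors / total_bases
        assert abs(rate - 0.02) < 3 * np.sqrt(0.02 * 0.98 / total_bases)


class TestGcAndOrganelleBias:
    def test_gc_slope_gives_positive_rank_correlation(self):
        # 12 chromosomes spanning GC 0.34..0.56; sign test over 5 seeds
        plans = [
            ChromosomePlan(f"c{i:02d}", ((30_000, 0.34 + 0.02 * i),)) for i in range(12)
        ]
        ref = simulate_reference(plans, seed=77)
        g = reference_as_genotype(ref)
        lengths = {c.id: len(c) for c in ref.chromosomes}
        gc = [ref[cid].gc for cid in sorted(lengths)]
        params = MdaParams(log_sd=0.6, gc_slope=8.0, error_rate=0.0)
        for seed in range(5):
            _, truth = simulate_mda_reads([g], 6000, params, seed=seed)
            depth = depth_from_truth(truth, lengths)
            cov = [(depth[cid] > 0).mean() for cid in sorted(lengths)]
            assert gc_coverage_correlation(gc, cov).rho > 0

    def test_organelle_copy_number_boosts_depth(self, small_ref):
        g = reference_as_genotype(small_ref)
        lengths = {c.id: len(c) for c in small_ref.chromosomes}
        params = MdaParams(log_sd=0.5, organelle_copy_number=20.0, error_rate=0.0)
        _, truth = simulate_mda_reads([g], 4000, params, seed=4)
        depth = depth_from_truth(truth, lengths)
        organelle_depth = depth["mito"].mean()
        genome_depth = sum(d.sum() for d in depth.values()) / sum(lengths.values())
        assert organelle_depth > genome_depth


class TestFastqIO:
    def test_roundtrip(self, uniform_reads, tmp_path):
        reads, _ = uniform_reads
        p = tmp_path / "r.fastq"
        write_fastq(reads[:50], str(p))
        back = read_fastq(str(p))
        assert back == reads[:50]

    def test_malformed_record_index_reported(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r0\nACGT\n+\n????\nXr1\nACGT\n+\n????\n")
        with pytest.raises(ValueError, match="record 1"):
            read_fastq(str(p))
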