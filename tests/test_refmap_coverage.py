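import numpy as np
import pytest

from conftest import alignments_from_truth
from picomet.refmap import consensus, coverage_profile, window_tracks
from picomet.refmap.mapper import ReadAlignment
from picomet.synthdata import ChromosomePlan, GenotypeSpec, MdaParams, plant_genotypes, simulate_mda_reads, simulate_reference
from picomet.synthdata.genotypes import reference_as_genotype


def _mk_aln(read_id, chrom, start, seq, mismatches=0):
    return ReadAlignment(
        read_id=read_id, chrom=chrom, ref_start=start, strand="+",
        cigar=[("M", len(seq))], seq=seq, mismatches=mismatches,
        score=2.0 * len(seq), identity=1.0, aligned_len=len(seq),
    )


@pytest.fixture()
def tiny_ref():
    return {"c1": "ACGT" * 250}  # 1000 bp


class TestCoverageProfile:
    def test_empty_input(self, tiny_ref):
        prof = coverage_profile([], tiny_ref)
        assert prof.chromosomes["c1"].coverage_fraction == 0
        assert prof.chromosomes["c1"].coverage_depth == 0

    def test_single_alignment_arithmetic(self, tiny_ref):
        aln = _mk_aln("r", "c1", 100, tiny_ref["c1"][100:200])
        prof = coverage_profile([aln], tiny_ref)
        c = prof.chromosomes["c1"]
        assert c.coverage_fraction == pytest.approx(0.10)
        assert c.coverage_depth == pytest.approx(0.10)
        assert c.covered_bp == 100

    def test_covered_bp_matches_positional_oracle(self, tiny_ref):
        rng = np.random.default_rng(5)
        alns, covered = [], set()
        for i in range(40):
            start = int(rng.integers(0, 900))
            length = int(rng.integers(20, 100))
            end = min(start + length, 1000)
            alns.append(_mk_aln(f"r{i}", "c1", start, tiny_ref["c1"][start:end]))
            covered |= set(range(start, end))
        prof = coverage_profile(alns, tiny_ref)
        assert prof.chromosomes["c1"].covered_bp == len(covered)
        assert prof.chromosomes["c1"].depth.sum() == sum(
            a.ref_end - a.ref_start for a in alns
        )

    def test_fraction_monotone_under_union(self, tiny_ref):
        rng = np.random.default_rng(6)
        alns = []
        prev = 0.0
        for i in range(20):
            start = int(rng.integers(0, 950))
            alns.append(_mk_aln(f"r{i}", "c1", start, tiny_ref["c1"][start : start + 50]))
            frac = coverage_profile(alns, tiny_ref).chromosomes["c1"].coverage_fraction
            assert frac >= prev
            prev = frac

    def test_identical_sites_100_for_perfect_reads(self, tiny_ref):
        alns = [_mk_aln("r", "c1", 0, tiny_ref["c1"][:500])]
        prof = coverage_profile(alns, tiny_ref)
        assert prof.chromosomes["c1"].identical_sites_pct == pytest.approx(100.0)

    def test_genome_fraction_is_weighted_mean(self):
        seqs = {"a": "A" * 1000, "b": "C" * 3000}
        alns = [_mk_aln("r1", "a", 0, "A" * 500), _mk_aln("r2", "b", 0, "C" * 600)]
        prof = coverage_profile(alns, seqs)
        assert prof.coverage_fraction == pytest.approx((500 + 600) / 4000)

    def test_unknown_chromosome_rejected(self, tiny_ref):
        with pytest.raises(KeyError):
            coverage_profile([_mk_aln("r", "zz", 0, "ACGT")], tiny_ref)


class TestConsensus:
    def test_majority_base(self, tiny_ref):
        alns = [_mk_aln(f"r{i}", "c1", 10, "AAAA") for i in range(3)]
        cons, depth = consensus(alns, tiny_ref)
        assert cons["c1"][10:14] == "AAAA"
        assert list(depth["c1"][10:14]) == [3, 3, 3, 3]

    def test_zero_coverage_takes_reference(self, tiny_ref):
        cons, depth = consensus([], tiny_ref)
        assert cons["c1"] == tiny_ref["c1"]
        assert depth["c1"].sum() == 0

    def test_tie_takes_reference(self):
        seqs = {"c1": "AAAA"}
        alns = [_mk_aln("r1", "c1", 0, "AATA"), _mk_aln("r2", "c1", 0, "AAAA")]
        cons, _ = consensus(alns, seqs)
        assert cons["c1"] == "AAAA"  # T vs A tie at position 2 resolves to reference

    def test_clear_majority_overrides_reference(self):
        seqs = {"c1": "AAAA"}
        alns = [_mk_aln(f"r{i}", "c1", 0, "AGAA") for i in range(3)]
        cons, _ = consensus(alns, seqs)
        assert cons["c1"] == "AGAA"

    def test_planted_genotype_recovered(self, small_ref):
        specs = [GenotypeSpec("g", 1.0, 0.005)]
        genomes, truth_vars = plant_genotypes(small_ref, specs, seed=31)
        reads, truth = simulate_mda_reads(
            genomes, int(20 * small_ref.total_length / 420), MdaParams(log_sd=0.0, error_rate=0.0), seed=32
        )
        alns = alignments_from_truth(reads, truth)
        cons, depth = consensus(alns, small_ref.sequences)
        n_ok = n_cov = 0
        for cid, seq in genomes[0].chromosomes.items():
            covered = depth[cid] > 0
            arr_g = np.frombuffer(seq.encode(), dtype=np.uint8)
            arr_c = np.frombuffer(cons[cid].encode(), dtype=np.uint8)
            n_ok += int((arr_g[covered] == arr_c[covered]).sum())
            n_cov += int(covered.sum())
        assert n_ok / n_cov >= 0.999


class TestWindowTracks:
    def test_window_partition(self):
        seqs = {"c1": "ACGT" * 3000}  # 12 kbp
        depth = {"c1": np.zeros(12_000)}
        rows = window_tracks(depth, seqs, window=5000)
        assert [(r["start"], r["end"]) for r in rows] == [(0, 5000), (5000, 10_000), (10_000, 12_000)]

    def test_uniform_depth(self):
        seqs = {"c1": "ACGT" * 3000}
        depth = {"c1": np.full(12_000, 7.0)}
        rows = window_tracks(depth, seqs, window=5000)
        assert all(r["mean_depth"] == pytest.approx(7.0) for r in rows)

    def test_tripartite_gc_visible(self, small_ref):
        depth = {c.id: np.zeros(len(c)) for c in small_ref.chromosomes}
        rows = window_tracks(depth, small_ref.sequences, window=2000)
        mid = [r for r in rows if r["chrom"] == "chr2" and 9000 <= r["start"] < 15_000]
        assert mid and all(abs(r["gc"] - 0.39) < 0.04 for r in mid)

    def test_window_floor(self, small_ref):
        depth = {c.id: np.zeros(len(c)) for c in small_ref.chromosomes}
        with pytest.raises(ValueError):
            window_tracks(depth, small_ref.sequences, window=50)
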