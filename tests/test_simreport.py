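import numpy as np
import pytest

from picomet.simreport import (
    anchored_align,
    gene_panel_similarity,
    identity_report,
    mask_low_coverage,
)
from picomet.simreport.identity import IdentityRow, weighted_total
from picomet.simreport.report import coverage_table, read_stats
from picomet.synthdata.reference import Feature
from picomet.synthdata.reads import ReadRecord


def _random_dna(n, rng):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture()
def triple():
    rng = np.random.default_rng(1)
    ref = _random_dna(5000, rng)
    a = list(ref)
    for p in rng.choice(5000, 25, replace=False):
        a[p] = "ACGT"[("ACGT".index(a[p]) + 1) % 4]
    return ref, "".join(a), ref  # B identical to ref


class TestAnchoredAlign:
    def test_identical_triple(self):
        s = "ACGT" * 100
        aln = anchored_align("c", s, s, s)
        assert len(aln) == 400

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            anchored_align("c", "ACGT", "ACG", "ACGT")

    def test_planted_differences_are_the_non_identical_columns(self, triple):
        ref, a, b = triple
        aln = anchored_align("c", ref, a, b)
        diffs = {i for i in range(len(ref)) if ref[i] != a[i]}
        m = mask_low_coverage(aln, np.full(5000, 20), np.full(5000, 20), 10)
        row = identity_report([m], []).rows[0]
        assert row.pct_three_way == pytest.approx((1 - len(diffs) / 5000) * 100)


class TestMaskLowCoverage:
    def test_all_above_threshold_unchanged(self, triple):
        ref, a, b = triple
        aln = anchored_align("c", ref, a, b)
        m = mask_low_coverage(aln, np.full(5000, 12), np.full(5000, 15), 10)
        assert len(m) == 5000 and m.intervals == [(0, 5000)]

    def test_one_sample_below_everywhere_empty(self, triple):
        ref, a, b = triple
        aln = anchored_align("c", ref, a, b)
        m = mask_low_coverage(aln, np.full(5000, 12), np.full(5000, 9), 10)
        assert len(m) == 0

    def test_retained_count_matches_and_oracle(self, triple):
        ref, a, b = triple
        aln = anchored_align("c", ref, a, b)
        rng = np.random.default_rng(2)
        for _ in range(100):
            da = rng.integers(0, 20, 5000)
            db = rng.integers(0, 20, 5000)
            md = int(rng.integers(1, 15))
            m = mask_low_coverage(aln, da, db, md)
            assert len(m) == int(((da >= md) & (db >= md)).sum())

    def test_mismatched_lengths_rejected(self, triple):
        ref, a, b = triple
        aln = anchored_align("c", ref, a, b)
        with pytest.raises(ValueError):
            mask_low_coverage(aln, np.full(4999, 12), np.full(5000, 12), 10)

    def test_masking_monotone_in_min_depth(self, triple):
        ref, a, b = triple
        aln = anchored_align("c", ref, a, b)
        rng = np.random.default_rng(3)
        da = rng.integers(0, 25, 5000)
        db = rng.integers(0, 25, 5000)
        lengths = [len(mask_low_coverage(aln, da, db, d)) for d in range(1, 20)]
        assert lengths == sorted(lengths, reverse=True)


class TestIdentityReport:
    def test_all_identical_is_100(self):
        s = "ACGT" * 500
        aln = anchored_align("c", s, s, s)
        m = mask_low_coverage(aln, np.full(2000, 20), np.full(2000, 20))
        rep = identity_report([m], [])
        assert rep.total.pct_three_way == pytest.approx(100.0)
        assert rep.total.pct_a_b == pytest.approx(100.0)

    def test_three_way_bounded_by_pairwise(self, triple):
        ref, a, b = triple
        rng = np.random.default_rng(4)
        b2 = list(b)
        for p in rng.choice(5000, 40, replace=False):
            b2[p] = "ACGT"[("ACGT".index(b2[p]) + 2) % 4]
        aln = anchored_align("c", ref, a, "".join(b2))
        m = mask_low_coverage(aln, np.full(5000, 20), np.full(5000, 20))
        r = identity_report([m], []).rows[0]
        assert r.pct_three_way <= min(r.pct_ref_a, r.pct_ref_b, r.pct_a_b) + 1e-9

    def test_column_count_oracle(self, triple):
        ref, a, b = triple
        aln = anchored_align("c", ref, a, b)
        m = mask_low_coverage(aln, np.full(5000, 20), np.full(5000, 20))
        r = identity_report([m], []).rows[0]
        expected = sum(1 for i in range(5000) if ref[i] == a[i] == b[i]) / 5000 * 100
        assert r.pct_three_way == pytest.approx(expected)

    def test_cds_split_follows_annotation(self, triple):
        ref, a, b = triple
        feats = [Feature("cds1", "c", 1000, 3000, "CDS")]
        aln = anchored_align("c", ref, a, b)
        m = mask_low_coverage(aln, np.full(5000, 20), np.full(5000, 20))
        r = identity_report([m], feats).rows[0]
        assert r.length_cds == 2000 and r.length_noncds == 3000

    def test_weighted_total_formula(self):
        rows = [
            IdentityRow("chromosome_1", 78_022, 0, 0, 96.7, 0, 0, 0, 0, 0),
            IdentityRow("chromosome_2", 158_544, 0, 0, 95.8, 0, 0, 0, 0, 0),
            IdentityRow("chromosome_3", 123_912, 0, 0, 96.7, 0, 0, 0, 0, 0),
        ]
        total = weighted_total(rows)
        assert total.length == 360_478
        assert total.pct_three_way == pytest.approx(96.3, abs=0.05)

    def test_empty_masked_rejected(self):
        with pytest.raises(ValueError):
            identity_report([], [])


class TestGenePanel:
    def test_verbatim_gene_found_at_100(self, triple):
        ref, a, b = triple
        genes = {"g1": ref[1000:2200]}
        res = gene_panel_similarity(genes, {"contig": ref})
        assert res.genes[0].found
        assert res.genes[0].pct_identity == pytest.approx(100.0)

    def test_absent_gene_not_found(self, triple):
        ref, _, _ = triple
        rng = np.random.default_rng(5)
        res = gene_panel_similarity({"g": _random_dna(800, rng)}, {"contig": ref})
        assert not res.genes[0].found

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            gene_panel_similarity({}, {"c": "ACGT"})

    def test_planted_divergence_recovered(self):
        # 30 genes at 2% divergence -> mean identity ~98%
        rng = np.random.default_rng(6)
        genes, contigs = {}, {}
        for i in range(30):
            g = _random_dna(600, rng)
            mutated = list(g)
            for p in rng.choice(600, 12, replace=False):
                mutated[p] = "ACGT"[("ACGT".index(mutated[p]) + 1) % 4]
            genes[f"g{i}"] = g
            contigs[f"c{i}"] = _random_dna(100, rng) + "".join(mutated) + _random_dna(100, rng)
        res = gene_panel_similarity(genes, contigs)
        assert res.n_found == 30
        sigma = np.sqrt(0.02 * 0.98 / 600) * 100 / np.sqrt(30)
        assert abs(res.mean_identity() - 98.0) < 3 * sigma + 0.2


class TestReadStatsAndTables:
    def test_mean_is_total_over_count(self):
        reads = [ReadRecord(f"r{i}", "ACGT" * (i + 1), "?" * 4 * (i + 1)) for i in range(10)]
        s = read_stats(reads)
        assert s["mean_len"] == round(s["total_bp"] / s["n_reads"])

    def test_coverage_table_totals_row(self, single_chrom_ref, uniform_reads):
        from conftest import alignments_from_truth
        from picomet.refmap.coverage import coverage_profile

        reads, truth = uniform_reads
        alns = alignments_from_truth(reads, truth)
        prof = coverage_profile(alns, single_chrom_ref.sequences)
        gc = single_chrom_ref.gc_by_chromosome()
        df = coverage_table(prof, gc)
        body = df[df["chrom"] != "total"]
        total = df[df["chrom"] == "total"].iloc[0]
        assert total["n_reads"] == body["n_reads"].sum()
        assert total["covered_bp"] == body["covered_bp"].sum()
        assert total["coverage_pct"] == pytest.approx(
            body["covered_bp"].sum() / body["length_bp"].sum() * 100, abs=0.01
        )
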