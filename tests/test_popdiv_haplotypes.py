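import numpy as np
import pytest

from conftest import alignments_from_truth
from picomet.popdiv import call_variants, min_haplotypes, pileup
from picomet.refmap.mapper import ReadAlignment
from picomet.synthdata import GenotypeSpec, MdaParams, plant_genotypes, simulate_mda_reads
from picomet.synthdata.genotypes import reference_as_genotype


def _aln(read_id, start, seq, chrom="c1"):
    return ReadAlignment(read_id, chrom, start, "+", [("M", len(seq))], seq, 0, 2.0 * len(seq), 1.0, len(seq))


REF = {"c1": "A" * 200}


def _reads_with(signature: dict[int, str], n: int, prefix: str, span=(50, 150)):
    out = []
    for i in range(n):
        seq = list(REF["c1"][span[0] : span[1]])
        for pos, alt in signature.items():
            seq[pos - span[0]] = alt
        out.append(_aln(f"{prefix}{i}", span[0], "".join(seq)))
    return out


class TestMinHaplotypes:
    def test_all_reference_reads_single_haplotype(self):
        alns = _reads_with({}, 10, "r")
        hset = min_haplotypes(alns, REF, ("c1", 50, 150))
        assert hset.n_min == 1
        assert hset.haplotypes[0].is_reference

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            min_haplotypes([], REF, ("c1", 50, 150))

    def test_two_group_structure(self):
        # reference-like reads + a 3-change group + a 1-change group; the
        # 1-change group cannot stand alone and merges into a declared
        # haplotype, so n_min reflects the two recurrent sequences
        ref_reads = _reads_with({}, 12, "ref")
        three = _reads_with({60: "T", 90: "G", 120: "C"}, 8, "three")
        one = _reads_with({60: "T"}, 3, "one")
        hset = min_haplotypes(ref_reads + three + one, REF, ("c1", 50, 150))
        assert hset.n_min == 2
        non_ref = next(h for h in hset.haplotypes if not h.is_reference)
        assert non_ref.signature == frozenset({(60, "T"), (90, "G"), (120, "C")})
        # the one-change reads merged somewhere, all reads accounted for
        assert sum(len(h.read_ids) for h in hset.haplotypes) == hset.n_informative

    def test_one_change_reads_merge_to_matching_haplotype(self):
        ref_reads = _reads_with({}, 10, "ref")
        hap = _reads_with({60: "T", 90: "G"}, 6, "hap")
        partial = _reads_with({60: "T", 90: "G"}, 1, "p")  # below min_reads on its own? same sig joins group
        hset = min_haplotypes(ref_reads + hap + partial, REF, ("c1", 50, 150))
        non_ref = next(h for h in hset.haplotypes if not h.is_reference)
        assert len(non_ref.read_ids) == 7

    def test_frequencies_sum_to_one_over_informative(self):
        ref_reads = _reads_with({}, 9, "ref")
        hap = _reads_with({60: "T", 90: "G"}, 6, "hap")
        hset = min_haplotypes(ref_reads + hap, REF, ("c1", 50, 150))
        assert sum(h.frequency for h in hset.haplotypes) == pytest.approx(1.0)
        assert hset.n_informative == 15

    def test_n_min_non_decreasing_with_reads(self):
        ref_reads = _reads_with({}, 10, "ref")
        hap = _reads_with({60: "T", 90: "G"}, 6, "hap")
        nested = [ref_reads, ref_reads + hap[:2], ref_reads + hap]
        n_prev = 0
        for subset in nested:
            n = min_haplotypes(subset, REF, ("c1", 50, 150)).n_min
            assert n >= n_prev
            n_prev = n

    def test_zero_error_single_genotype_no_variants(self, single_chrom_ref):
        g = reference_as_genotype(single_chrom_ref)
        reads, truth = simulate_mda_reads([g], 1500, MdaParams(log_sd=0.0, error_rate=0.0), seed=41)
        alns = alignments_from_truth(reads, truth)
        cols = pileup(alns, single_chrom_ref.sequences, ("chr1", 20_000, 21_000))
        assert call_variants(cols) == []


class TestFrequencyRecovery:
    @pytest.mark.parametrize("mix", [(0.85, 0.15), (0.59, 0.41)])
    def test_planted_mixture_recovered(self, small_ref, mix):
        """20-seed parameter recovery of planted two-genotype mixtures."""
        p_major, p_minor = mix
        recovered = []
        n_inf_total = 0
        for seed in range(20):
            specs = [GenotypeSpec("major", p_major, 0.0), GenotypeSpec("minor", p_minor, 0.008)]
            genomes, snp_truth = plant_genotypes(small_ref, specs, seed=1000 + seed)
            minor_pos = sorted(
                v.position for v in snp_truth if v.genotype == "minor" and v.chrom == "chr1"
            )
            region = None
            for i in range(len(minor_pos) - 1):
                gap = minor_pos[i + 1] - minor_pos[i]
                if 2000 < minor_pos[i] and gap < 250:
                    region = ("chr1", minor_pos[i] - 40, minor_pos[i + 1] + 40)
                    break
            if region is None:
                continue
            reads, truth = simulate_mda_reads(
                genomes, 6000, MdaParams(log_sd=0.0, error_rate=0.0), seed=2000 + seed
            )
            alns = alignments_from_truth(reads, truth)
            # 10% frequency floor: the 15% genotype sits exactly on the
            # default floor, which would censor half the replicates
            hset = min_haplotypes(alns, small_ref.sequences, region, min_freq=0.10)
            non_ref = [h for h in hset.haplotypes if not h.is_reference]
            if not non_ref or hset.n_informative < 20:
                continue
            recovered.append(max(h.frequency for h in non_ref))
            n_inf_total += hset.n_informative
        assert len(recovered) >= 8
        mean_inf = n_inf_total / len(recovered)
        sigma = np.sqrt(p_minor * p_major / mean_inf) / np.sqrt(len(recovered))
        assert abs(np.mean(recovered) - p_minor) < 3 * sigma + 0.02
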