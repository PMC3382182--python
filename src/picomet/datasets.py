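"""Bundled example dataset: per-chromosome mapping summary of two
flow-sorted picoeukaryote field samples ("s1", "s2") recruited to a
21-nuclear-chromosome + 2-organelle reference genome, plus the matching
read-set statistics and a three-chromosome consensus-identity summary.

These numbers are published summary statistics shipped as package data
so that desk-scale analytics (rank correlations, aggregate coverage,
weighted identity) can be exercised and cross-checked without any
external download.  Every derived figure in the package is recomputed
from these row-level values, never copied.
"""

from __future__ import annotations

TOTAL_REFERENCE_LENGTH = 15_034_870

# columns: chrom, category, length_bp, gc_pct,
#   s1: n_reads, covered_bp, coverage_pct, depth, identical_pct
#   s2: n_reads, covered_bp, coverage_pct, depth, identical_pct
CHROMOSOME_SUMMARY: list[dict] = [
    {"chrom": "chromosome_1", "category": "nuclear", "length_bp": 1_352_574, "gc_pct": 48.87,
     "s1": {"n_reads": 17_507, "covered_bp": 887_310, "coverage_pct": 64.40, "depth": 4.61, "identical_pct": 95.50},
     "s2": {"n_reads": 44_115, "covered_bp": 1_260_242, "coverage_pct": 90.60, "depth": 11.26, "identical_pct": 90.50}},
    {"chrom": "chromosome_2", "category": "nuclear", "length_bp": 1_122_692, "gc_pct": 48.55,
     "s1": {"n_reads": 76_131, "covered_bp": 763_755, "coverage_pct": 65.50, "depth": 23.96, "identical_pct": 91.70},
     "s2": {"n_reads": 45_448, "covered_bp": 1_045_505, "coverage_pct": 89.90, "depth": 13.84, "identical_pct": 88.90}},
    {"chrom": "chromosome_3", "category": "nuclear", "length_bp": 1_089_374, "gc_pct": 48.62,
     "s1": {"n_reads": 23_634, "covered_bp": 747_266, "coverage_pct": 67.00, "depth": 7.68, "identical_pct": 94.50},
     "s2": {"n_reads": 36_961, "covered_bp": 1_032_050, "coverage_pct": 91.80, "depth": 11.66, "identical_pct": 90.00}},
    {"chrom": "chromosome_4", "category": "nuclear", "length_bp": 1_037_991, "gc_pct": 48.29,
     "s1": {"n_reads": 14_217, "covered_bp": 613_146, "coverage_pct": 58.00, "depth": 4.76, "identical_pct": 95.70},
     "s2": {"n_reads": 19_099, "covered_bp": 914_632, "coverage_pct": 86.10, "depth": 6.22, "identical_pct": 91.90}},
    {"chrom": "chromosome_5a", "category": "nuclear", "length_bp": 550_167, "gc_pct": 48.34,
     "s1": {"n_reads": 4_559, "covered_bp": 299_250, "coverage_pct": 53.40, "depth": 2.95, "identical_pct": 96.50},
     "s2": {"n_reads": 13_535, "covered_bp": 504_509, "coverage_pct": 89.20, "depth": 8.44, "identical_pct": 90.90}},
    {"chrom": "chromosome_5b", "category": "nuclear", "length_bp": 467_783, "gc_pct": 48.58,
     "s1": {"n_reads": 2_152, "covered_bp": 222_904, "coverage_pct": 47.00, "depth": 1.58, "identical_pct": 97.20},
     "s2": {"n_reads": 13_712, "covered_bp": 437_480, "coverage_pct": 90.60, "depth": 10.02, "identical_pct": 90.00}},
    {"chrom": "chromosome_6", "category": "nuclear", "length_bp": 989_707, "gc_pct": 48.30,
     "s1": {"n_reads": 17_733, "covered_bp": 677_434, "coverage_pct": 66.90, "depth": 6.25, "identical_pct": 94.30},
     "s2": {"n_reads": 29_292, "covered_bp": 915_584, "coverage_pct": 90.10, "depth": 10.06, "identical_pct": 90.60}},
    {"chrom": "chromosome_7", "category": "nuclear", "length_bp": 955_054, "gc_pct": 48.42,
     "s1": {"n_reads": 49_892, "covered_bp": 608_532, "coverage_pct": 61.60, "depth": 17.54, "identical_pct": 93.30},
     "s2": {"n_reads": 30_116, "covered_bp": 845_293, "coverage_pct": 85.80, "depth": 10.63, "identical_pct": 90.30}},
    {"chrom": "chromosome_8", "category": "nuclear", "length_bp": 937_610, "gc_pct": 48.54,
     "s1": {"n_reads": 10_892, "covered_bp": 545_919, "coverage_pct": 57.00, "depth": 4.09, "identical_pct": 95.70},
     "s2": {"n_reads": 29_489, "covered_bp": 841_544, "coverage_pct": 86.80, "depth": 10.70, "identical_pct": 89.90}},
    {"chrom": "chromosome_9", "category": "nuclear", "length_bp": 895_347, "gc_pct": 48.51,
     "s1": {"n_reads": 17_995, "covered_bp": 636_008, "coverage_pct": 69.30, "depth": 7.07, "identical_pct": 93.80},
     "s2": {"n_reads": 23_672, "covered_bp": 806_272, "coverage_pct": 87.50, "depth": 9.05, "identical_pct": 90.70}},
    {"chrom": "chromosome_10", "category": "nuclear", "length_bp": 794_148, "gc_pct": 48.38,
     "s1": {"n_reads": 20_350, "covered_bp": 533_074, "coverage_pct": 65.30, "depth": 9.03, "identical_pct": 93.70},
     "s2": {"n_reads": 19_996, "covered_bp": 743_420, "coverage_pct": 90.90, "depth": 8.66, "identical_pct": 90.20}},
    {"chrom": "chromosome_11", "category": "nuclear", "length_bp": 741_502, "gc_pct": 48.62,
     "s1": {"n_reads": 26_119, "covered_bp": 516_527, "coverage_pct": 67.50, "depth": 12.50, "identical_pct": 92.40},
     "s2": {"n_reads": 12_368, "covered_bp": 634_120, "coverage_pct": 83.70, "depth": 5.70, "identical_pct": 92.50}},
    {"chrom": "chromosome_12a", "category": "nuclear", "length_bp": 201_229, "gc_pct": 47.52,
     "s1": {"n_reads": 2_066, "covered_bp": 106_614, "coverage_pct": 52.00, "depth": 3.66, "identical_pct": 96.30},
     "s2": {"n_reads": 3_707, "covered_bp": 180_588, "coverage_pct": 87.40, "depth": 6.31, "identical_pct": 91.40}},
    {"chrom": "chromosome_12b", "category": "nuclear", "length_bp": 511_334, "gc_pct": 48.55,
     "s1": {"n_reads": 19_985, "covered_bp": 391_273, "coverage_pct": 74.20, "depth": 13.84, "identical_pct": 92.10},
     "s2": {"n_reads": 15_530, "covered_bp": 483_876, "coverage_pct": 91.70, "depth": 10.45, "identical_pct": 89.30}},
    {"chrom": "chromosome_13", "category": "nuclear", "length_bp": 706_576, "gc_pct": 48.54,
     "s1": {"n_reads": 90_889, "covered_bp": 363_302, "coverage_pct": 48.00, "depth": 45.29, "identical_pct": 91.30},
     "s2": {"n_reads": 17_849, "covered_bp": 584_838, "coverage_pct": 80.20, "depth": 8.54, "identical_pct": 91.00}},
    {"chrom": "chromosome_14", "category": "nuclear", "length_bp": 662_304, "gc_pct": 42.24,
     "s1": {"n_reads": 1_873, "covered_bp": 264_505, "coverage_pct": 39.30, "depth": 0.93, "identical_pct": 97.70},
     "s2": {"n_reads": 12_822, "covered_bp": 433_085, "coverage_pct": 63.70, "depth": 6.41, "identical_pct": 93.90}},
    {"chrom": "chromosome_15", "category": "nuclear", "length_bp": 519_535, "gc_pct": 48.13,
     "s1": {"n_reads": 6_320, "covered_bp": 324_598, "coverage_pct": 61.10, "depth": 4.30, "identical_pct": 94.80},
     "s2": {"n_reads": 10_865, "covered_bp": 473_213, "coverage_pct": 88.80, "depth": 7.14, "identical_pct": 91.60}},
    {"chrom": "chromosome_16", "category": "nuclear", "length_bp": 481_036, "gc_pct": 48.08,
     "s1": {"n_reads": 14_765, "covered_bp": 268_376, "coverage_pct": 52.30, "depth": 10.67, "identical_pct": 94.00},
     "s2": {"n_reads": 14_526, "covered_bp": 445_984, "coverage_pct": 87.50, "depth": 10.16, "identical_pct": 89.90}},
    {"chrom": "chromosome_17", "category": "nuclear", "length_bp": 465_570, "gc_pct": 47.66,
     "s1": {"n_reads": 18_609, "covered_bp": 283_891, "coverage_pct": 58.50, "depth": 14.21, "identical_pct": 91.80},
     "s2": {"n_reads": 10_433, "covered_bp": 390_682, "coverage_pct": 81.30, "depth": 7.63, "identical_pct": 90.60}},
    {"chrom": "chromosome_18", "category": "nuclear", "length_bp": 310_170, "gc_pct": 46.97,
     "s1": {"n_reads": 9_003, "covered_bp": 226_193, "coverage_pct": 70.50, "depth": 10.30, "identical_pct": 91.20},
     "s2": {"n_reads": 5_203, "covered_bp": 269_409, "coverage_pct": 84.60, "depth": 5.67, "identical_pct": 91.00}},
    {"chrom": "chromosome_19", "category": "nuclear", "length_bp": 146_238, "gc_pct": 41.65,
     "s1": {"n_reads": 73, "covered_bp": 10_779, "coverage_pct": 7.20, "depth": 0.13, "identical_pct": 99.30},
     "s2": {"n_reads": 129, "covered_bp": 11_504, "coverage_pct": 7.70, "depth": 0.21, "identical_pct": 99.10}},
    {"chrom": "chloroplast", "category": "organelle", "length_bp": 54_761, "gc_pct": 41.12,
     "s1": {"n_reads": 21, "covered_bp": 5_029, "coverage_pct": 6.90, "depth": 0.09, "identical_pct": 99.70},
     "s2": {"n_reads": 46, "covered_bp": 12_675, "coverage_pct": 17.30, "depth": 0.20, "identical_pct": 99.40}},
    {"chrom": "mitochondrion", "category": "organelle", "length_bp": 42_168, "gc_pct": 39.97,
     "s1": {"n_reads": 261, "covered_bp": 30_825, "coverage_pct": 72.20, "depth": 1.74, "identical_pct": 97.00},
     "s2": {"n_reads": 3_470, "covered_bp": 43_650, "coverage_pct": 99.90, "depth": 21.90, "identical_pct": 91.70}},
]

# read-set statistics for the two samples
SAMPLE_READS: dict[str, dict] = {
    "s1": {"n_reads": 671_249, "total_bp": 287_619_051, "min_len": 40, "max_len": 2_015, "gc_pct": 46.7},
    "s2": {"n_reads": 671_832, "total_bp": 279_858_614, "min_len": 40, "max_len": 2_044, "gc_pct": 46.5},
}

# three-chromosome masked consensus-identity summary (alignment length and
# three-way identical-site percentage, whole alignment)
IDENTITY_SUMMARY: list[dict] = [
    {"chrom": "chromosome_1", "length": 78_022, "length_cds": 70_644, "length_noncds": 7_376,
     "pct_three_way": 96.7, "pct_cds": 97.5, "pct_noncds": 89.5,
     "pct_ref_s1": 97.8, "pct_ref_s2": 97.3, "pct_s1_s2": 98.3},
    {"chrom": "chromosome_2", "length": 158_544, "length_cds": 142_659, "length_noncds": 19_681,
     "pct_three_way": 95.8, "pct_cds": 97.0, "pct_noncds": 87.2,
     "pct_ref_s1": 97.0, "pct_ref_s2": 96.6, "pct_s1_s2": 97.4},
    {"chrom": "chromosome_3", "length": 123_912, "length_cds": 115_661, "length_noncds": 12_823,
     "pct_three_way": 96.7, "pct_cds": 97.4, "pct_noncds": 89.5,
     "pct_ref_s1": 97.8, "pct_ref_s2": 97.4, "pct_s1_s2": 97.8},
]


def nuclear_rows() -> list[dict]:
    return [r for r in CHROMOSOME_SUMMARY if r["category"] == "nuclear"]


def sample_columns(sample: str, key: str) -> list[float]:
    """Column extractor, nuclear chromosomes only."""
    return [r[sample][key] for r in nuclear_rows()]
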