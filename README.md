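# picomet

Analytics for flow-sorted, whole-genome-amplified (MDA) picoeukaryote
metagenomes, exercised end to end on a synthetic sorted-cell metagenome
generator so no external data are needed.

The package reimplements, as a tested reusable pipeline:

- **`picomet.synthdata`** — synthetic multi-chromosome reference genomes
  with controlled GC structure (standard nuclear chromosomes, a
  tri-partite low-GC outlier, low-GC organelles), coexisting genotypes
  differing by SNPs and rRNA intron presence/absence, ortholog protein
  families over a genus/class taxonomy, and MDA-biased 454-style read
  sets — all with full ground-truth tracking.
- **`picomet.refmap`** — quality trimming, greedy seed-and-extend read
  mapping (identity ≥ 90% over ≥ 40 bp), per-base coverage profiles
  (coverage fraction / depth / identical sites), reference-projected
  consensus calling, per-window GC/depth tracks, and tie-aware Spearman
  GC–coverage correlation.
- **`picomet.taxassign`** — the ortholog-threshold taxonomic classifier:
  per-protein minimum identity/length threshold matrices computed from
  ortholog pairs at genus and class rank (default floor 80% identity
  over 50 aa for genome-specific proteins), six-frame translated search,
  non-redundant merging of local hits per query–subject pair,
  hierarchical genus → class → best-hit-default assignment, a minimal
  LCA classifier (min score 35, top-percent 10%, min support 5), an rRNA
  contig screen (> 200 bp hits), and leave-one-out false-positive
  validation.
- **`picomet.popdiv`** — pileups, filtered single-nucleotide variant
  calls (depth ≥ 5, ≥ 2 supporting reads, frequency ≥ 15%),
  minimum-haplotype decomposition (recurrent changes shared at ≥ 2
  positions by ≥ 2 reads), and intron presence/absence genotyping from
  junction-spanning reads.
- **`picomet.simreport`** — depth-masked (≥ 10× in both samples)
  three-way identity reports with CDS/non-CDS splits, gene-panel
  nucleotide similarity, and tabular run reports.

`picomet.datasets` ships a published per-chromosome mapping summary of
two field samples (row-level values only) so the desk-scale analytics
can be validated offline.

## CLI

All stages are exposed through one entry point:

```bash
picomet simulate ref       --config sim.yaml --seed 1 --out-fasta ref.fa --out-gff ref.gff3
picomet simulate community --config sim.yaml --seed 1 --out-fastq reads.fastq --out-truth truth.tsv
picomet simulate proteins  --config prot.yaml --seed 1 --out-fasta prot.fa \
                           --out-taxonomy tax.tsv --out-groups groups.tsv
picomet trim      --fastq reads.fastq --out trimmed.fastq
picomet map       --fastq trimmed.fastq --ref ref.fa --out-sam aln.sam
picomet coverage  --sam aln.sam --ref ref.fa --out coverage.tsv
picomet correlate --table coverage.tsv
picomet tracks    --sam aln.sam --ref ref.fa --out tracks.tsv
picomet thresholds --proteins prot.fa --taxonomy tax.tsv --groups groups.tsv --out matrix.tsv
picomet classify  --queries contigs.fa --proteins prot.fa --taxonomy tax.tsv \
                  --groups groups.tsv --out assignments.tsv
picomet lca       --hits hits.tsv --taxonomy parents.tsv --out lca.tsv
picomet screen-rrna --contigs contigs.fa --rrna rrna.fa --out rrna_hits.tsv
picomet validate-fp --proteins prot.fa --taxonomy tax.tsv --groups groups.tsv \
                    --held-out gA1 --genome gA1.fa --n-fragments 500 --seed 1
picomet variants   --sam aln.sam --ref ref.fa --region chr1:1-20000 --out variants.tsv
picomet haplotypes --sam aln.sam --ref ref.fa --region chr1:5000-5400 --out haplotypes.tsv
picomet introns    --fastq reads.fastq --without-intron exon.fa --with-intron exon_intron.fa
picomet similarity --ref ref.fa --gff ref.gff3 --sam-a a.sam --sam-b b.sam --out identity.tsv
picomet genes      --genes panel.fa --contigs contigs.fa --out genes.tsv
picomet report     --fastq reads.fastq --sam aln.sam --ref ref.fa --out-dir report/
```

A minimal simulation config:

```yaml
chromosomes:
  - {id: chr1, segments: [{length: 20000, gc: 0.48}], rrna_operon: true}
  - {id: chr2, segments: [{length: 4000, gc: 0.47}, {length: 4000, gc: 0.39}]}
genotypes:
  - {label: major, abundance: 0.85}
  - {label: minor, abundance: 0.15, snp_rate: 0.01}
mda: {log_sd: 1.0, gc_slope: 0.0, error_rate: 0.005}
n_reads: 10000
```

## Conventions

- Coordinates are 0-based half-open internally; 1-based in SAM and TSV
  reports.
- Alignment identity everywhere = matches / columns between the first
  and last doubly-aligned column; internal gaps count as mismatch
  columns, end gaps are excluded.
- Consensus sequences are reference-projected: ties and uncovered
  columns take the reference base, so multi-sample comparisons are
  column-wise exact.
- All generators are deterministic given (spec, seed).
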