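"""MDA-biased 454-style read simulation with truth tracking.

Coverage bias model: per-chromosome anchor points every `anchor_spacing`
bp receive i.i.d. lognormal amplification factors (sd `log_sd` in log
space) which are linearly interpolated between anchors, producing
long-range coverage waves.  A GC effect multiplies the weight by
exp(gc_slope * (local GC - genome GC)) computed on 1 kbp windows, and
organelle chromosomes get a copy-number multiplier.  Read lengths follow
a truncated lognormal; sequencing error is substitution-only at a
configurable rate; qualities are a constant Q30 symbol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from picomet.synthdata.genotypes import GenotypeGenome

GC_WINDOW = 1000
_COMP = bytes.maketrans(b"ACGT", b"TGCA")
Q30 = "?"  # phred+33
_ALT = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


@dataclass(frozen=True)
class MdaParams:
    anchor_spacing: int = 5000
    log_sd: float = 1.0
    gc_slope: float = 0.0
    organelle_copy_number: float = 1.0
    # (min, max, mean, shape): truncated lognormal read-length law
    read_length_law: tuple[int, int, int, float] = (40, 2044, 420, 0.35)
    error_rate: float = 0.005

    def __post_init__(self) -> None:
        if self.log_sd < 0:
            raise ValueError("log_sd must be >= 0")
        lo, hi, mean, _ = self.read_length_law
        if not lo <= mean <= hi:
            raise ValueError("read length law needs min <= mean <= max")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate outside [0, 1)")


@dataclass(frozen=True)
class ReadRecord:
    id: str
    sequence: str
    quality: str


@dataclass(frozen=True)
class TruthRow:
    read_id: str
    genome: str
    chrom: str
    start: int
    end: int
    strand: str
    errors: int


@dataclass
class TruthTable:
    rows: list[TruthRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def by_read(self) -> dict[str, TruthRow]:
        return {r.read_id: r for r in self.rows}

    def genome_fractions(self) -> dict[str, float]:
        n = len(self.rows)
        out: dict[str, float] = {}
        for r in self.rows:
            out[r.genome] = out.get(r.genome, 0) + 1
        return {k: v / n for k, v in out.items()} if n else {}

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tgenome\tchrom\tstart\tend\tstrand\terrors\n")
            for r in self.rows:
                fh.write(
                    f"{r.read_id}\t{r.genome}\t{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t{r.errors}\n"
                )


def _gc_profile(seq_bytes: np.ndarray, window: int = GC_WINDOW) -> np.ndarray:
    """Per-base local GC fraction, piecewise constant on `window`-bp blocks."""
    is_gc = (seq_bytes == ord("G")) | (seq_bytes == ord("C"))
    n = len(is_gc)
    out = np.empty(n, dtype=np.float64)
    for s in range(0, n, window):
        e = min(s + window, n)
        out[s:e] = is_gc[s:e].mean()
    return out


def _position_weights(
    seq: str, category: str, genome_gc: float, params: MdaParams, rng: np.random.Generator
) -> np.ndarray:
    n = len(seq)
    sb = np.frombuffer(seq.encode(), dtype=np.uint8)
    n_anchor = max(n // params.anchor_spacing + 2, 2)
    anchors = np.arange(n_anchor) * params.anchor_spacing
    log_factors = rng.normal(0.0, params.log_sd, size=n_anchor) if params.log_sd > 0 else np.zeros(n_anchor)
    w = np.exp(np.interp(np.arange(n), anchors, log_factors))
    if params.gc_slope != 0.0:
        w *= np.exp(params.gc_slope * (_gc_profile(sb) - genome_gc))
    if category == "organelle":
        w *= params.organelle_copy_number
    return w


def _sample_lengths(n: int, law: tuple[int, int, int, float], rng: np.random.Generator) -> np.ndarray:
    lo, hi, mean, shape = law
    if shape <= 0:
        return np.full(n, mean, dtype=np.int64)
    mu = np.log(mean) - shape**2 / 2
    lengths = np.exp(rng.normal(mu, shape, size=n))
    # resample out-of-range draws rather than clip, keeping the law's tail shape
    bad = (lengths < lo) | (lengths > hi)
    while bad.any():
        lengths[bad] = np.exp(rng.normal(mu, shape, size=int(bad.sum())))
        bad = (lengths < lo) | (lengths > hi)
    return lengths.astype(np.int64)


def simulate_mda_reads(
    genomes: Sequence[GenotypeGenome],
    n_reads: int,
    params: MdaParams,
    seed: int,
) -> tuple[list[ReadRecord], TruthTable]:
    """Draw `n_reads` reads from a genotype community under the MDA bias model.

    Read start positions are drawn with probability proportional to
    genotype abundance x interpolated anchor factor x GC multiplier x
    organelle multiplier.  Coordinates in the truth table refer to the
    emitting genotype's own chromosome coordinates.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    total = sum(g.abundance for g in genomes)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"genome abundances sum to {total}, expected 1")
    reads: list[ReadRecord] = []
    truth = TruthTable()
    if n_reads == 0:
        return reads, truth

    rng = np.random.default_rng(seed)
    # flat list of (genome, chrom) with per-base weights
    units: list[tuple[GenotypeGenome, str, np.ndarray]] = []
    unit_mass: list[float] = []
    for g in genomes:
        genome_gc = g.gc()
        for chrom_id, seq in sorted(g.chromosomes.items()):
            w = _position_weights(seq, g.categories[chrom_id], genome_gc, params, rng)
            units.append((g, chrom_id, w))
            unit_mass.append(g.abundance * float(w.sum()) / max(g.total_length, 1) * len(seq))
    mass = np.array(unit_mass)
    # normalize per genome so that abundance governs genome share exactly
    by_label: dict[str, float] = {}
    for (g, _, _), m in zip(units, mass):
        by_label[g.label] = by_label.get(g.label, 0.0) + m
    probs = np.array(
        [g.abundance * m / by_label[g.label] for (g, _, _), m in zip(units, mass)]
    )
    probs /= probs.sum()

    counts = rng.multinomial(n_reads, probs)
    lengths = _sample_lengths(n_reads, params.read_length_law, rng)
    idx = 0
    lo = params.read_length_law[0]
    for (g, chrom_id, w), count in zip(units, counts):
        if count == 0:
            continue
        seq = g.chromosomes[chrom_id]
        p = w / w.sum()
        starts = rng.choice(len(seq), size=count, p=p)
        for s in starts:
            length = int(lengths[idx])
            end = min(int(s) + length, len(seq))
            if end - int(s) < lo:  # too close to the chromosome end: shift left
                s = max(0, len(seq) - length)
                end = min(int(s) + length, len(seq))
            frag = seq[int(s) : end]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                frag = frag.encode().translate(_COMP)[::-1].decode()
            n_err = rng.binomial(len(frag), params.error_rate) if params.error_rate > 0 else 0
            if n_err:
                fb = list(frag)
                for pos in rng.choice(len(frag), size=n_err, replace=False):
                    fb[pos] = _ALT[fb[pos]][rng.integers(0, 3)]
                frag = "".join(fb)
            rid = f"read{idx:07d}"
            reads.append(ReadRecord(rid, frag, Q30 * len(frag)))
            truth.rows.append(TruthRow(rid, g.label, chrom_id, int(s), end, strand, int(n_err)))
            idx += 1
    return reads, truth


def write_fastq(reads: Sequence[ReadRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str) -> list[ReadRecord]:
    """Minimal strict 4-line FASTQ reader; raises with the record index on malformed input."""
    out: list[ReadRecord] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) % 4 != 0:
        raise ValueError("FASTQ file length not a multiple of 4 lines")
    for i in range(0, len(lines), 4):
        rec = i // 4
        if not lines[i].startswith("@") or lines[i + 2][:1] != "+":
            raise ValueError(f"malformed FASTQ record {rec}")
        seq, qual = lines[i + 1], lines[i + 3]
        if len(seq) != len(qual):
            raise ValueError(f"malformed FASTQ record {rec}: seq/qual length mismatch")
        out.append(ReadRecord(lines[i][1:].split()[0], seq, qual))
    return out
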