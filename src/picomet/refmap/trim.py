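"""Quality trimming of reads: probability-threshold end trimming, no ambiguity."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from picomet.synthdata.reads import ReadRecord

_UNAMBIGUOUS = set("ACGT")


def _error_probs(quality: str) -> list[float]:
    return [10 ** (-(ord(q) - 33) / 10) for q in quality]


@dataclass
class TrimResult:
    reads: list[ReadRecord] = field(default_factory=list)
    n_dropped_ambiguous: int = 0
    n_dropped_empty: int = 0


def trim_reads(reads: Sequence[ReadRecord], error_prob_threshold: float = 0.01) -> TrimResult:
    """Trim both read ends at an error-probability threshold and drop
    reads whose retained body contains ambiguity codes.

    The maximal prefix and suffix consisting of bases with error
    probability above the threshold are removed.  Reads that trim to
    nothing are dropped and counted separately.
    """
    out = TrimResult()
    for rec in reads:
        probs = _error_probs(rec.quality)
        start = 0
        while start < len(probs) and probs[start] > error_prob_threshold:
            start += 1
        end = len(probs)
        while end > start and probs[end - 1] > error_prob_threshold:
            end -= 1
        if end <= start:
            out.n_dropped_empty += 1
            continue
        body = rec.sequence[start:end]
        if any(b not in _UNAMBIGUOUS for b in body):
            out.n_dropped_ambiguous += 1
            continue
        out.reads.append(ReadRecord(rec.id, body, rec.quality[start:end]))
    return out
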