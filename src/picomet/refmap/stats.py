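"""Tie-aware Spearman correlation between chromosome GC and coverage."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_one_sided: float
    p_two_sided: float
    n: int


def gc_coverage_correlation(gc: Sequence[float], coverage: Sequence[float]) -> CorrelationResult:
    """Spearman's rho (Pearson correlation of average ranks) with a
    one-sided p-value from the t approximation at n-2 degrees of freedom.

    The one-sided p tests for positive association; the two-sided value
    is also reported."""
    x = np.asarray(gc, dtype=float)
    y = np.asarray(coverage, dtype=float)
    if x.shape != y.shape:
        raise ValueError("input lists must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: an input has zero variance")
    rho, p_two = sps.spearmanr(x, y)
    rho = float(rho)
    if abs(rho) == 1.0:
        p_one = 0.0 if rho > 0 else 1.0
    else:
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
        p_one = float(sps.t.sf(t, df=n - 2))
    return CorrelationResult(rho=rho, p_one_sided=p_one, p_two_sided=float(p_two), n=n)
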