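"""Statistical tests applied to lineage data.

Fisher's exact test is computed exactly: with the margins of a 2x2 table
fixed, the tables form a one-parameter hypergeometric family, and the
two-sided p-value is the total probability of tables no more probable
than the observed one. The arithmetic uses exact rationals, so the result
is deterministic to the last bit.

The Mann-Whitney rank-sum test delegates to scipy (exact distribution at
small sample sizes without ties, normal approximation with tie correction
otherwise); the method used is recorded in the result.
"""
from __future__ import annotations

import dataclasses
import warnings
from fractions import Fraction
from math import comb

import numpy as np
from scipy import stats as sps


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of lineages (rows = group) with/without co-dividing siblings."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    @classmethod
    def from_array(cls, table) -> "ContingencyTable2x2":
        t = np.asarray(table, dtype=int)
        if t.shape != (2, 2):
            raise ValueError("expected a 2x2 table")
        return cls(int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1]))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table.

    Sums the hypergeometric probabilities (fixed margins) of every table
    whose probability does not exceed the observed table's. A zero margin
    makes the table uninformative: p = 1 with a warning.
    """
    t = table if isinstance(table, ContingencyTable2x2) else ContingencyTable2x2.from_array(table)
    a, b, c, d = t.a, t.b, t.c, t.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if 0 in (r1, r2, c1, b + d):
        warnings.warn("zero margin: Fisher's test is uninformative, p = 1",
                      stacklevel=2)
        return 1.0
    denom = comb(n, c1)
    k_lo, k_hi = max(0, c1 - r2), min(r1, c1)
    probs = {
        k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        for k in range(k_lo, k_hi + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


@dataclasses.dataclass(frozen=True)
class MannWhitneyResult:
    statistic: float  # U of the first sample
    pvalue: float
    method: str


def mann_whitney(sample_a, sample_b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact p-value when the smaller sample has <= 8 observations and the
    pooled data is tie-free; normal approximation with tie correction
    otherwise. Two identical samples yield p = 1 with a warning.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both samples, p = 1",
                      stacklevel=2)
        return MannWhitneyResult(len(a) * len(b) / 2.0, 1.0, "degenerate")
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(a), len(b)) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), method)
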