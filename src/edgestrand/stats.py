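"""Exact binomial significance of edge-strand assignment.

Each scored sheet is one assay.  Under random assignment the probability
of naming a wrong strand as an edge is at most one half (exactly one half
for four-stranded sheets, which have 2 edges among 4 strands; smaller for
larger sheets, so the test is conservative).  The p-value is therefore the
exact fair-coin cumulative probability of at most k failures in n assays,

    p = sum_{i=0..k} C(n, i) / 2**n,

evaluated with integer binomial coefficients and a single exact rational
division at the end — no floating-point accumulation, no incomplete-beta
shortcut.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

__all__ = ["BinomialTest", "binomial_p", "binomial_p_exact"]


def binomial_p_exact(n: int, k: int) -> Fraction:
    """Exact rational P(failures <= k | n fair assays)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, {n}], got {k}")
    return Fraction(sum(comb(n, i) for i in range(k + 1)), 1 << n)


def binomial_p(n: int, k: int) -> float:
    """P(failures <= k | n fair assays) as a float (exact sum, one division)."""
    return float(binomial_p_exact(n, k))


@dataclass(frozen=True)
class BinomialTest:
    """Result of an edge-prediction batch: n assays, k failures, exact p."""

    n: int
    k: int

    @property
    def accuracy(self) -> float:
        return (self.n - self.k) / self.n

    @property
    def p_value(self) -> float:
        return binomial_p(self.n, self.k)
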