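"""Enumeration of SOF intervals and per-residue coverage.

A SOF ("sequence optimized for folding") is a contiguous sub-sequence
S(i, j) of a protein chain whose free-peptide nucleon mass is a perfect
square.  The span j - i is bounded: by default spans 1..20, i.e. peptides
of 2 to 21 residues.  Span 0 (single residues) is excluded by default,
which removes the lone length-1 SOF, free cysteine (mass 121 = 11**2).

Coverage V(p) counts how many SOF intervals contain chain position p;
strand scores are means of V over strand residues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .masses import DEFAULT_TABLE, ONE_TO_THREE, ResidueMassTable, UnknownResidueError

__all__ = [
    "SOFInterval",
    "CoverageProfile",
    "SkipReport",
    "is_perfect_square",
    "enumerate_sof",
    "coverage_profile",
    "sequence_from_text",
    "sof_table_tsv",
]


def is_perfect_square(n: int) -> bool:
    """True iff ``n`` is k**2 for an integer k >= 0 (exact integer isqrt)."""
    if n < 0:
        raise ValueError(f"is_perfect_square requires n >= 0, got {n}")
    r = math.isqrt(n)
    return r * r == n


@dataclass(frozen=True, order=True)
class SOFInterval:
    """Closed interval [start, end] of 1-based chain positions with its mass."""

    start: int
    end: int
    mass: int

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def n_residues(self) -> int:
        return self.end - self.start + 1


@dataclass
class SkipReport:
    """Counts of intervals skipped because they contain unknown-mass residues."""

    skipped_intervals: int = 0
    unknown_codes: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class CoverageProfile:
    """Per-position SOF coverage V for chain positions 1..L."""

    values: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, position: int) -> int:
        """Coverage at 1-based chain position."""
        if not 1 <= position <= len(self.values):
            raise IndexError(f"position {position} outside chain 1..{len(self.values)}")
        return self.values[position - 1]

    def mean(self, start: int, end: int) -> float:
        """Mean V over the closed 1-based position range [start, end]."""
        if not (1 <= start <= end <= len(self.values)):
            raise IndexError(f"range {start}..{end} outside chain 1..{len(self.values)}")
        window = self.values[start - 1 : end]
        return sum(window) / len(window)


def enumerate_sof(
    sequence: Sequence[str],
    min_span: int = 1,
    max_span: int = 20,
    table: ResidueMassTable = DEFAULT_TABLE,
    skip_report: SkipReport | None = None,
) -> list[SOFInterval]:
    """All square-mass intervals [i, j] with j - i in [min_span, max_span].

    Masses are accumulated incrementally per start position; intervals
    containing a residue with no defined mass are skipped (and recorded in
    ``skip_report`` if given), never treated as mass zero.  Output is sorted
    by (start, end).
    """
    if len(sequence) == 0:
        raise ValueError("enumerate_sof requires a non-empty sequence")
    if min_span < 0 or max_span < min_span:
        raise ValueError(f"invalid span bounds [{min_span}, {max_span}]")

    L = len(sequence)
    terminal = table.water_mass if table.with_water else 0
    # residue masses with None marking unknown codes
    res_mass: list[int | None] = []
    for code in sequence:
        try:
            res_mass.append(table.residue(code))
        except UnknownResidueError as err:
            res_mass.append(None)
            if skip_report is not None:
                skip_report.unknown_codes.add(err.code)

    out: list[SOFInterval] = []
    for i in range(L):
        if res_mass[i] is None:
            if skip_report is not None:
                skip_report.skipped_intervals += max(0, min(max_span, L - 1 - i) - min_span + 1)
            continue
        mass = res_mass[i] + terminal
        for j in range(i + 1, min(L, i + max_span + 1)):
            mj = res_mass[j]
            if mj is None:
                if skip_report is not None:
                    skip_report.skipped_intervals += max(
                        0, min(i + max_span, L - 1) - max(j, i + min_span) + 1
                    )
                break
            mass += mj
            if j - i < min_span:
                continue
            if is_perfect_square(mass):
                out.append(SOFInterval(i + 1, j + 1, mass))
        if min_span == 0 and is_perfect_square(res_mass[i] + terminal):
            out.append(SOFInterval(i + 1, i + 1, res_mass[i] + terminal))
    out.sort()
    return out


def coverage_profile(sequence_length: int, sof_list: Iterable[SOFInterval]) -> CoverageProfile:
    """Per-position counts of covering SOF intervals (difference-array sweep)."""
    if sequence_length < 1:
        raise ValueError("sequence_length must be >= 1")
    diff = [0] * (sequence_length + 1)
    for iv in sof_list:
        if not (1 <= iv.start <= iv.end <= sequence_length):
            raise ValueError(f"interval {iv.start}..{iv.end} outside chain 1..{sequence_length}")
        diff[iv.start - 1] += 1
        diff[iv.end] -= 1
    values = []
    running = 0
    for d in diff[:-1]:
        running += d
        values.append(running)
    return CoverageProfile(tuple(values))


def sequence_from_text(text: str) -> list[str]:
    """Parse a sequence given as FASTA / 1-letter string / 3-letter tokens.

    Returns ordered 3-letter codes.  FASTA header lines are ignored; a
    whitespace-separated token of length 3 is taken as a 3-letter code,
    anything else as a run of 1-letter codes.
    """
    tokens: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith((">", ";")):
            continue
        tokens.extend(line.split())
    if not tokens:
        raise ValueError("no sequence found in input")
    codes: list[str] = []
    for tok in tokens:
        if len(tok) == 3 and tok.upper() in {*ONE_TO_THREE.values(), "MSE", "UNK"}:
            codes.append(tok.upper())
        else:
            for ch in tok:
                try:
                    codes.append(ONE_TO_THREE[ch.upper()])
                except KeyError:
                    codes.append("UNK")
    return codes


def sof_table_tsv(sof_list: Iterable[SOFInterval]) -> str:
    """Plot-ready TSV of SOF intervals: start, end, span, mass, sqrt_mass."""
    lines = ["start\tend\tspan\tmass\tsqrt_mass"]
    for iv in sof_list:
        lines.append(f"{iv.start}\t{iv.end}\t{iv.span}\t{iv.mass}\t{math.isqrt(iv.mass)}")
    return "\n".join(lines) + "\n"
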