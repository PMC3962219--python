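"""Sheet/strand eligibility filters and per-strand V_m scores.

Eligibility mirrors the screening used to build the prediction statistics:
strands of three or fewer residues are ignored, and a sheet is scored only
if more than three strands survive.  V_m is the arithmetic mean of the
per-residue SOF coverage V over the strand's SEQRES positions.

Filter order is configurable: ``sheet_min_strands_basis="filtered"``
(default, the stricter reading) requires >= 4 strands *after* dropping
short strands; ``"declared"`` applies the sheet-size test to the strand
count as recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .pdbio import ChainRecord, NumberingGapError, SheetRecord, StrandRecord, strand_indices
from .sof import CoverageProfile

__all__ = [
    "MIN_STRAND_RESIDUES",
    "MIN_SHEET_STRANDS",
    "StrandScore",
    "eligible_sheets",
    "score_sheet",
]

#: Strands of 3 or fewer residues are not considered.
MIN_STRAND_RESIDUES = 4
#: Only sheets with more than three (eligible) strands are scored.
MIN_SHEET_STRANDS = 4


@dataclass(frozen=True)
class StrandScore:
    strand: StrandRecord
    residue_indices: tuple[int, ...]
    v_values: tuple[int, ...]

    @property
    def v_m(self) -> float:
        return sum(self.v_values) / len(self.v_values)

    @property
    def n_residues(self) -> int:
        return len(self.residue_indices)


def _strand_length(chain: ChainRecord, strand: StrandRecord) -> int | None:
    try:
        b, e = strand_indices(chain, strand)
    except NumberingGapError as err:
        warnings.warn(str(err))
        return None
    return e - b + 1


def eligible_sheets(
    sheets: list[SheetRecord],
    chain: ChainRecord,
    basis: str = "filtered",
) -> list[SheetRecord]:
    """Sheets that qualify for scoring, with short strands removed.

    Strands on other chains or with unmappable extents are dropped with a
    warning.  Returned sheets are new records whose strands keep their
    original registration ordinals.  Barrel (closed-sheet) exclusion is
    geometric and lives in :mod:`edgestrand.predict`.
    """
    if basis not in ("filtered", "declared"):
        raise ValueError(f"unknown basis {basis!r}")
    out: list[SheetRecord] = []
    for sheet in sheets:
        kept: list[StrandRecord] = []
        for strand in sheet.strands:
            if strand.chain_id != chain.chain_id:
                continue
            length = _strand_length(chain, strand)
            if length is None:
                continue
            if length >= MIN_STRAND_RESIDUES:
                kept.append(strand)
        count = len(kept) if basis == "filtered" else len(sheet.strands)
        if kept and count >= MIN_SHEET_STRANDS:
            out.append(
                SheetRecord(sheet.sheet_id, kept, declared_strand_count=sheet.declared_strand_count)
            )
    return out


def score_sheet(
    sheet: SheetRecord,
    profile: CoverageProfile,
    chain: ChainRecord,
) -> list[StrandScore]:
    """One StrandScore per strand, in registration order.

    Unmappable strands are dropped with a warning; callers should re-check
    eligibility if that matters to them.
    """
    scores: list[StrandScore] = []
    for strand in sheet.strands:
        try:
            b, e = strand_indices(chain, strand)
        except NumberingGapError as err:
            warnings.warn(f"dropping strand {strand.strand_ordinal} of sheet "
                          f"{sheet.sheet_id}: {err}")
            continue
        indices = tuple(range(b, e + 1))
        scores.append(
            StrandScore(
                strand=strand,
                residue_indices=indices,
                v_values=tuple(profile[i] for i in indices),
            )
        )
    return scores
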