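"""End-to-end per-entry workflow: parse -> SOF -> score -> predict.

This is the glue the CLI and batch evaluation use.  For one PDB entry it
selects the analysis chain (first DBREF protein chain of >= 50 residues),
enumerates SOF intervals over its SEQRES sequence, scores every eligible
open sheet and applies the base or improved rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .knot2d import flag_knotted_strands
from .pdbio import Structure, parse_structure, select_analysis_chain
from .predict import (
    EdgePrediction,
    InsufficientCoordinatesError,
    PredictionConfig,
    detect_closed_sheet,
    predict_edge_base,
    predict_edge_improved,
    true_edge_ordinals,
)
from .scoring import MIN_SHEET_STRANDS, StrandScore, eligible_sheets, score_sheet
from .sof import CoverageProfile, SkipReport, coverage_profile, enumerate_sof

__all__ = ["SheetResult", "EntryResult", "analyze_entry", "analyze_structure"]


@dataclass
class SheetResult:
    sheet_id: str
    prediction: EdgePrediction
    true_edges: set[int]
    scores: list[StrandScore]

    @property
    def correct(self) -> bool:
        return self.prediction.counted_ordinal in self.true_edges


@dataclass
class EntryResult:
    entry_id: str
    chain_id: str
    profile: CoverageProfile
    sheets: list[SheetResult]
    skipped_sheets: list[str] = field(default_factory=list)  # "<id>: reason"
    skip_report: SkipReport = field(default_factory=SkipReport)


def analyze_structure(
    structure: Structure,
    config: PredictionConfig = PredictionConfig(),
    entry_id: str = "?",
    min_span: int = 1,
    max_span: int = 20,
) -> EntryResult:
    chain = select_analysis_chain(structure)
    skip = SkipReport()
    sof = enumerate_sof(chain.sequence, min_span=min_span, max_span=max_span, skip_report=skip)
    profile = coverage_profile(len(chain.sequence), sof)

    result = EntryResult(entry_id, chain.chain_id, profile, [], skip_report=skip)
    for sheet in eligible_sheets(structure.sheets, chain):
        try:
            closed = detect_closed_sheet(sheet, structure.ca_coordinates, config.barrel_cutoff)
        except InsufficientCoordinatesError:
            closed = False  # no coordinates: fall back to declared (open) topology
        if closed:
            result.skipped_sheets.append(f"{sheet.sheet_id}: closed sheet (barrel)")
            continue
        scores = score_sheet(sheet, profile, chain)
        if len(scores) < MIN_SHEET_STRANDS:
            result.skipped_sheets.append(f"{sheet.sheet_id}: fewer than 4 scorable strands")
            continue
        if config.use_knot_exclusion:
            flags = flag_knotted_strands(sheet, chain, structure.ca_coordinates, structure.helices)
            try:
                prediction = predict_edge_improved(scores, flags, config)
            except ValueError as err:
                warnings.warn(f"sheet {sheet.sheet_id}: {err}; falling back to base rule")
                prediction = predict_edge_base(scores, config)
        else:
            prediction = predict_edge_base(scores, config)
        result.sheets.append(
            SheetResult(sheet.sheet_id, prediction, true_edge_ordinals(sheet), scores)
        )
    return result


def analyze_entry(
    pdb_text: str,
    config: PredictionConfig = PredictionConfig(),
    entry_id: str = "?",
    min_span: int = 1,
    max_span: int = 20,
) -> EntryResult:
    """Parse PDB text and run the full prediction workflow on it."""
    return analyze_structure(
        parse_structure(pdb_text), config, entry_id=entry_id, min_span=min_span, max_span=max_span
    )
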