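"""Synthetic stand-in for the transthyretin worked example.

Human transthyretin (prealbumin) is the classic small beta-sandwich: two
four-stranded sheets, each with two edge and two central strands.  This
module carries a *synthetic reconstruction* of that worked example —
the canonical mature human transthyretin sequence (UniProt P02766,
127 residues) together with the two sheets' strand extents and their
edge/central labels — rather than a deposited coordinate file, so the
worked example runs fully offline.  Residue numbering is the mature-chain
numbering (position 1 = Gly1); all sixteen strand-boundary residues below
sit at the stated positions of this sequence.

Note the deposited crystallographic entries of transthyretin predate the
modern reference sequence and can differ from it at a few positions, so
per-strand mean coverages computed here can deviate in the second decimal
from values derived from a specific deposited entry; the strand *ranking*
and the predicted edge strands are robust to this.
"""

from __future__ import annotations

from dataclasses import dataclass

from .masses import ONE_TO_THREE
from .pdbio import StrandRecord
from .predict import EdgePrediction, PredictionConfig, predict_edge_base
from .scoring import StrandScore
from .sof import CoverageProfile, coverage_profile, enumerate_sof

__all__ = ["TRANSTHYRETIN_SEQUENCE", "TRANSTHYRETIN_SHEETS", "ReferenceStrand", "run_reference"]

#: Mature human transthyretin, 1-letter code (synthetic stand-in sequence).
TRANSTHYRETIN_SEQUENCE = (
    "GPTGTGESKCPLMVKVLDAVRGSPAINVAVHVFRKAADDTWEPFASGKTSESGELHGLTT"
    "EEEFVEGIYKVEIDTKSYWKALGISPFHEHAEVVFTANDSGPRRYTIAALLSPYSYSTTA"
    "VVTNPKE"
)


@dataclass(frozen=True)
class ReferenceStrand:
    begin: int  # 1-based mature-chain position, inclusive
    end: int
    label: str  # "E1", "C1", "C2", "E2"

    @property
    def is_edge(self) -> bool:
        return self.label.startswith("E")


#: The two four-stranded sheets, strands in registration order (edges at
#: the ends of each list, centrals in between).
TRANSTHYRETIN_SHEETS: dict[str, tuple[ReferenceStrand, ...]] = {
    "A": (
        ReferenceStrand(115, 123, "E1"),
        ReferenceStrand(103, 112, "C1"),
        ReferenceStrand(11, 18, "C2"),
        ReferenceStrand(53, 56, "E2"),
    ),
    "B": (
        ReferenceStrand(45, 49, "E1"),
        ReferenceStrand(28, 36, "C1"),
        ReferenceStrand(66, 74, "C2"),
        ReferenceStrand(90, 97, "E2"),
    ),
}


def run_reference(
    min_span: int = 1, max_span: int = 20, config: PredictionConfig = PredictionConfig()
) -> dict[str, object]:
    """Score the stand-in entry and predict one edge strand per sheet.

    Returns per-sheet V_m values keyed by strand extent, the prediction,
    and whether the predicted strand is a labelled edge.
    """
    codes = [ONE_TO_THREE[c] for c in TRANSTHYRETIN_SEQUENCE]
    profile: CoverageProfile = coverage_profile(
        len(codes), enumerate_sof(codes, min_span=min_span, max_span=max_span)
    )
    out: dict[str, object] = {"profile": profile, "sheets": {}}
    for sheet_id, strands in TRANSTHYRETIN_SHEETS.items():
        scores = []
        for ordinal, s in enumerate(strands, start=1):
            rec = StrandRecord(
                sheet_id=sheet_id,
                strand_ordinal=ordinal,
                chain_id="A",
                begin_residue=(s.begin, " "),
                end_residue=(s.end, " "),
            )
            idx = tuple(range(s.begin, s.end + 1))
            scores.append(
                StrandScore(rec, idx, tuple(profile[i] for i in idx))
            )
        prediction: EdgePrediction = predict_edge_base(scores, config)
        predicted = strands[prediction.counted_ordinal - 1]
        out["sheets"][sheet_id] = {
            "v_m": {f"{s.begin}-{s.end}": sc.v_m for s, sc in zip(strands, scores)},
            "labels": {f"{s.begin}-{s.end}": s.label for s in strands},
            "prediction": prediction,
            "predicted_extent": f"{predicted.begin}-{predicted.end}",
            "predicted_is_edge": predicted.is_edge,
        }
    return out
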