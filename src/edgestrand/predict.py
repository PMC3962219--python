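"""Edge-strand prediction rules and batch evaluation.

The base rule: if any strand of the sheet has mean coverage V_m in
[0, 0.34), the *lowest* V_m marks an edge strand (branch "low");
otherwise the *highest* V_m marks an edge strand (branch "high").
The 0.34 bound is strict.

The improved rule first strikes strands whose ends are tied into a 2D
knot (see :mod:`edgestrand.knot2d`) from the candidate set, then applies
the unchanged base rule to the remainder: an extreme V_m on a knotted
central strand is evidence about the knot, not about edge position.

Ground truth for an open sheet is the pair of strands at the ends of the
registration order (the strands hydrogen-bonded to a single neighbour).
Closed sheets (barrels) have no edge strands and are excluded; closure is
detected geometrically from the CA contact between the first and last
registration strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .pdbio import SheetRecord
from .scoring import StrandScore
from .stats import BinomialTest

__all__ = [
    "LOW_VM_THRESHOLD",
    "BARREL_CONTACT_CUTOFF",
    "PredictionConfig",
    "EdgePrediction",
    "ClosedSheetError",
    "InsufficientCoordinatesError",
    "predict_edge_base",
    "predict_edge_improved",
    "true_edge_ordinals",
    "detect_closed_sheet",
    "evaluate_predictions",
]

#: Upper bound (strict) of the low-V_m branch.
LOW_VM_THRESHOLD = 0.34
#: CA-CA contact distance (Angstrom) closing first and last strands into a barrel.
BARREL_CONTACT_CUTOFF = 5.5


class ClosedSheetError(ValueError):
    """A closed sheet (barrel) has no edge strands."""


class InsufficientCoordinatesError(ValueError):
    """CA coordinates required for a geometric test are missing."""


@dataclass(frozen=True)
class PredictionConfig:
    low_threshold: float = LOW_VM_THRESHOLD
    use_knot_exclusion: bool = False
    tie_policy: str = "report-all"  # or "first-in-order"
    barrel_cutoff: float = BARREL_CONTACT_CUTOFF

    def __post_init__(self) -> None:
        if self.low_threshold <= 0:
            raise ValueError("low_threshold must be positive")
        if self.tie_policy not in ("report-all", "first-in-order"):
            raise ValueError(f"unknown tie_policy {self.tie_policy!r}")


@dataclass
class EdgePrediction:
    sheet_id: str
    predicted_strand_ordinals: list[int]
    rule_branch: str  # "low" | "high"
    excluded_ordinals: list[int] = field(default_factory=list)
    v_m_by_ordinal: dict[int, float] = field(default_factory=dict)

    @property
    def counted_ordinal(self) -> int:
        """The single ordinal counted in evaluation (first in registration order)."""
        return min(self.predicted_strand_ordinals)


def _extreme(scores: Sequence[StrandScore], config: PredictionConfig) -> EdgePrediction:
    vm = {s.strand.strand_ordinal: s.v_m for s in scores}
    if min(vm.values()) < config.low_threshold:
        branch, target = "low", min(vm.values())
    else:
        branch, target = "high", max(vm.values())
    winners = sorted(o for o, v in vm.items() if v == target)
    if config.tie_policy == "first-in-order":
        winners = winners[:1]
    return EdgePrediction(
        sheet_id=scores[0].strand.sheet_id,
        predicted_strand_ordinals=winners,
        rule_branch=branch,
        v_m_by_ordinal=vm,
    )


def predict_edge_base(
    scores: Sequence[StrandScore], config: PredictionConfig = PredictionConfig()
) -> EdgePrediction:
    """Base rule: lowest V_m if it falls below the threshold, else highest."""
    if len(scores) < 4:
        raise ValueError(f"need >= 4 scored strands, got {len(scores)}")
    return _extreme(scores, config)


def predict_edge_improved(
    scores: Sequence[StrandScore],
    knot_flags: Iterable[int],
    config: PredictionConfig = PredictionConfig(),
) -> EdgePrediction:
    """Improved rule: strike knot-flagged strands, then apply the base rule."""
    if len(scores) < 4:
        raise ValueError(f"need >= 4 scored strands, got {len(scores)}")
    flags = set(knot_flags)
    ordinals = {s.strand.strand_ordinal for s in scores}
    candidates = [s for s in scores if s.strand.strand_ordinal not in flags]
    if not candidates:
        raise ValueError("all strands knot-flagged; no candidates remain")
    pred = _extreme(candidates, config)
    pred.excluded_ordinals = sorted(flags & ordinals)
    pred.v_m_by_ordinal = {s.strand.strand_ordinal: s.v_m for s in scores}
    return pred


def true_edge_ordinals(sheet: SheetRecord, closed: bool = False) -> set[int]:
    """Edge ordinals of an open sheet: the registration-order endpoints."""
    if closed:
        raise ClosedSheetError(f"sheet {sheet.sheet_id} is closed: no edge strands")
    ordinals = [s.strand_ordinal for s in sheet.strands]
    return {min(ordinals), max(ordinals)}


def detect_closed_sheet(
    sheet: SheetRecord,
    ca_coordinates: Mapping[tuple[str, tuple[int, str]], np.ndarray],
    contact_cutoff: float = BARREL_CONTACT_CUTOFF,
) -> bool:
    """True if first and last registration strands are in CA contact (barrel).

    Uses the minimum CA-CA distance between the two strands' residues.
    """
    first = sheet.strands[0]
    last = sheet.strands[-1]
    if first is last:
        return False

    def strand_cas(strand) -> list[np.ndarray]:
        b, e = strand.begin_residue, strand.end_residue
        out = []
        for (cid, key), xyz in ca_coordinates.items():
            if cid != strand.chain_id:
                continue
            if b[0] <= key[0] <= e[0]:
                out.append(xyz)
        return out

    a = strand_cas(first)
    b = strand_cas(last)
    if not a or not b:
        raise InsufficientCoordinatesError(
            f"sheet {sheet.sheet_id}: missing CA coordinates for end strands"
        )
    pa = np.asarray(a)
    pb = np.asarray(b)
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    return bool(d.min() < contact_cutoff)


def evaluate_predictions(
    predictions: Sequence[EdgePrediction],
    truths: Sequence[set[int]],
) -> BinomialTest:
    """Count correct assays: the counted ordinal must be a true edge.

    One assay per sheet; returns the exact binomial summary (n, k failures,
    accuracy, p-value under the fair-coin null).
    """
    if len(predictions) != len(truths):
        raise ValueError(
            f"{len(predictions)} predictions vs {len(truths)} truth sets"
        )
    if not predictions:
        raise ValueError("no predictions to evaluate")
    k = sum(
        1 for pred, truth in zip(predictions, truths) if pred.counted_ordinal not in truth
    )
    return BinomialTest(n=len(predictions), k=k)
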