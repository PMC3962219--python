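import numpy as np
import pytest
from hypothesis import given, strategies as st

from edgestrand.pdbio import SheetRecord, StrandRecord, select_analysis_chain
from edgestrand.predict import (
    ClosedSheetError,
    PredictionConfig,
    detect_closed_sheet,
    evaluate_predictions,
    predict_edge_base,
    predict_edge_improved,
    true_edge_ordinals,
)
from edgestrand.scoring import StrandScore


def scores_from_vm(vms):
    out = []
    for ordinal, vm in enumerate(vms, start=1):
        rec = StrandRecord("S", ordinal, "A", (ordinal * 10, " "), (ordinal * 10 + 5, " "))
        # constant per-residue coverage makes v_m equal the requested value
        out.append(StrandScore(rec, tuple(range(6)), (vm,) * 6))
    return out


class TestBaseRule:
    @pytest.mark.parametrize(
        "vms, branch, winner",
        [
            ([1.9, 4.3, 1.1, 1.0], "high", 2),
            ([3.0, 3.6, 2.8, 2.3], "high", 2),
            ([0.2, 1.0, 2.0, 3.0], "low", 1),
            ([0.34, 1.0, 2.0, 3.0], "high", 4),  # 0.34 itself is NOT in the low range
        ],
    )
    def test_branch_selection(self, vms, branch, winner):
        pred = predict_edge_base(scores_from_vm(vms))
        assert pred.rule_branch == branch
        assert pred.predicted_strand_ordinals == [winner]

    def test_exactly_one_branch_fires(self):
        for vms in ([0.1, 1, 1, 1], [0.5, 1, 2, 3], [0, 0, 0, 0]):
            pred = predict_edge_base(scores_from_vm(vms))
            assert (pred.rule_branch == "low") == (min(vms) < 0.34)

    def test_fewer_than_four_strands_rejected(self):
        with pytest.raises(ValueError):
            predict_edge_base(scores_from_vm([1, 2, 3]))

    def test_tie_policy(self):
        vms = [2.0, 5.0, 5.0, 1.0]
        pred = predict_edge_base(scores_from_vm(vms))
        assert pred.predicted_strand_ordinals == [2, 3]
        assert pred.counted_ordinal == 2
        first = predict_edge_base(scores_from_vm(vms), PredictionConfig(tie_policy="first-in-order"))
        assert first.predicted_strand_ordinals == [2]


class TestImprovedRule:
    def test_excluding_the_maximum_moves_the_prediction(self):
        pred = predict_edge_improved(scores_from_vm([1.9, 4.3, 1.1, 1.0]), {2})
        assert pred.rule_branch == "high"
        assert pred.predicted_strand_ordinals == [1]
        assert pred.excluded_ordinals == [2]

    def test_low_branch_after_exclusion(self):
        pred = predict_edge_improved(scores_from_vm([0.2, 0.1, 1.0, 2.0]), {2})
        assert pred.rule_branch == "low"
        assert pred.predicted_strand_ordinals == [1]

    @given(
        vms=st.lists(
            st.floats(min_value=0, max_value=6, allow_nan=False), min_size=4, max_size=8
        )
    )
    def test_no_flags_equals_base_rule(self, vms):
        base = predict_edge_base(scores_from_vm(vms))
        improved = predict_edge_improved(scores_from_vm(vms), set())
        assert improved.predicted_strand_ordinals == base.predicted_strand_ordinals
        assert improved.rule_branch == base.rule_branch

    def test_all_flagged_rejected(self):
        with pytest.raises(ValueError):
            predict_edge_improved(scores_from_vm([1, 2, 3, 4]), {1, 2, 3, 4})


class TestTruth:
    def test_open_sheet_edges_are_registration_endpoints(self):
        def sheet(n):
            return SheetRecord(
                "S", [StrandRecord("S", i, "A", (i, " "), (i + 4, " ")) for i in range(1, n + 1)]
            )

        assert true_edge_ordinals(sheet(4)) == {1, 4}
        assert true_edge_ordinals(sheet(8)) == {1, 8}

    def test_closed_sheet_has_no_edges(self):
        sheet = SheetRecord("S", [StrandRecord("S", 1, "A", (1, " "), (5, " "))])
        with pytest.raises(ClosedSheetError):
            true_edge_ordinals(sheet, closed=True)


class TestBarrelDetection:
    def test_planar_sheet_is_open(self, open_structure):
        (sheet,) = open_structure.sheets
        assert detect_closed_sheet(sheet, open_structure.ca_coordinates) is False

    def test_barrel_is_closed(self, barrel_structure):
        (sheet,) = barrel_structure.sheets
        assert detect_closed_sheet(sheet, barrel_structure.ca_coordinates) is True

    def test_cutoff_monotonicity(self, barrel_structure):
        (sheet,) = barrel_structure.sheets
        assert detect_closed_sheet(sheet, barrel_structure.ca_coordinates, contact_cutoff=4.0) is False


class TestEvaluation:
    def predictions(self, outcomes):
        preds, truths = [], []
        for i, ok in enumerate(outcomes):
            from edgestrand.predict import EdgePrediction

            preds.append(EdgePrediction(f"S{i}", [1], "high"))
            truths.append({1, 4} if ok else {2, 4})
        return preds, truths

    def test_counts_and_accuracy(self):
        preds, truths = self.predictions([True, True, True, False])
        result = evaluate_predictions(preds, truths)
        assert (result.n, result.k) == (4, 1)
        assert result.accuracy == 0.75
        assert result.p_value == 0.3125

    def test_all_correct(self):
        preds, truths = self.predictions([True] * 5)
        result = evaluate_predictions(preds, truths)
        assert result.k == 0 and result.accuracy == 1.0

    def test_batch_reordering_invariance(self):
        preds, truths = self.predictions([True, False, True, True, False])
        base = evaluate_predictions(preds, truths)
        rev = evaluate_predictions(preds[::-1], truths[::-1])
        assert (base.n, base.k) == (rev.n, rev.k)

    def test_length_mismatch_rejected(self):
        preds, truths = self.predictions([True, False])
        with pytest.raises(ValueError):
            evaluate_predictions(preds, truths[:1])
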