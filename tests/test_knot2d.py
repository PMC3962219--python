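import numpy as np
import pytest

from edgestrand.knot2d import (
    AxisLine,
    DegeneratePlaneError,
    detect_2d_knot,
    end_perpendicular_axis,
    flag_knotted_strands,
    project_trace,
    sheet_axis,
)
from edgestrand.pdbio import StrandRecord, select_analysis_chain


def rotate(structure, seed=5):
    """Rigid-body rotate + translate every CA coordinate (new dict)."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    t = rng.normal(scale=20.0, size=3)
    return {k: Q @ v + t for k, v in structure.ca_coordinates.items()}


def trace_of(structure):
    chain = select_analysis_chain(structure)
    items = [
        (key, xyz)
        for (cid, key), xyz in structure.ca_coordinates.items()
        if cid == chain.chain_id
    ]
    items.sort(key=lambda kv: kv[0])
    return items


class TestSheetAxis:
    def test_planar_fixture_axis_runs_along_strand_stacking(self, open_structure):
        (sheet,) = open_structure.sheets
        axis = sheet_axis(sheet, open_structure.ca_coordinates)
        # ideal sheet: one perfectly collinear CA per strand exists
        per_strand_min = [
            min(float(axis.distance(xyz)[0]) for (cid, key), xyz in open_structure.ca_coordinates.items()
                if cid == s.chain_id and s.begin_residue[0] <= key[0] <= s.end_residue[0])
            for s in sheet.strands
        ]
        assert sum(per_strand_min) == pytest.approx(0.0, abs=1e-9)
        # the axis crosses the strand plane transversally, not along a strand
        assert abs(axis.direction @ np.array([0.0, 1.0, 0.0])) > 0.5

    def test_objective_invariant_under_rigid_motion(self, open_structure):
        (sheet,) = open_structure.sheets
        ca2 = rotate(open_structure)
        axis = sheet_axis(sheet, ca2)
        per_strand_min = [
            min(float(axis.distance(xyz)[0]) for (cid, key), xyz in ca2.items()
                if s.begin_residue[0] <= key[0] <= s.end_residue[0])
            for s in sheet.strands
        ]
        assert sum(per_strand_min) == pytest.approx(0.0, abs=1e-6)

    def test_missing_strand_coordinates_error(self, open_structure):
        (sheet,) = open_structure.sheets
        with pytest.raises(ValueError):
            sheet_axis(sheet, {})


class TestEndPerpendicularAxis:
    def strand_on_x(self):
        ca = {("A", (i, " ")): np.array([3.4 * (i - 1), 0.0, 0.0]) for i in range(1, 7)}
        rec = StrandRecord("S", 1, "A", (1, " "), (6, " "))
        return rec, ca

    def test_orthogonal_geometry_gives_z_normal(self):
        rec, ca = self.strand_on_x()
        axis = end_perpendicular_axis(rec, "N", np.array([0.0, 4.8, 0.0]), ca)
        assert abs(axis.direction @ np.array([0, 0, 1.0])) == pytest.approx(1.0)

    def test_collinear_plane_points_rejected(self):
        rec, ca = self.strand_on_x()
        with pytest.raises(DegeneratePlaneError):
            end_perpendicular_axis(rec, "C", np.array([50.0, 0.0, 0.0]), ca)

    def test_translation_invariance(self):
        rec, ca = self.strand_on_x()
        shift = np.array([10.0, -5.0, 2.0])
        moved = {k: v + shift for k, v in ca.items()}
        a = end_perpendicular_axis(rec, "N", np.array([0.0, 4.8, 0.0]), ca)
        b = end_perpendicular_axis(rec, "N", np.array([0.0, 4.8, 0.0]) + shift, moved)
        assert np.allclose(np.abs(a.direction), np.abs(b.direction))
        assert np.allclose(b.point - a.point, shift)


class TestDetect2DKnot:
    def make_trace(self, points):
        return [((i + 1, " "), np.asarray(p, dtype=float)) for i, p in enumerate(points)]

    def test_crossing_by_construction(self):
        # segment 0-1 of the "loop" crosses segment 3-4 of the trace in z-view
        trace = self.make_trace(
            [(0, 0, 0), (2, 2, 0), (3, 0, 0), (0, 2, 0), (2, 0, 0)]
        )
        axis = AxisLine(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        assert detect_2d_knot(trace, (0, 1), axis) is True

    def test_monotone_loop_has_no_crossing(self):
        trace = self.make_trace([(x, 0.2 * x, 0) for x in range(8)])
        axis = AxisLine(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        assert detect_2d_knot(trace, (2, 5), axis) is False

    def test_crossing_is_view_dependent(self):
        # two segments pass close in 3D but only overlap in the z-projection
        trace = self.make_trace(
            [(0, 0, 0), (2, 2, 0), (3, 0, 5), (0, 2, 5), (2, 0, 5)]
        )
        z_axis = AxisLine(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        y_axis = AxisLine(np.zeros(3), np.array([0.0, 1.0, 0.0]))
        assert detect_2d_knot(trace, (0, 1), z_axis) is True
        assert detect_2d_knot(trace, (0, 1), y_axis) is False

    def test_short_loop_warns_and_is_false(self):
        trace = self.make_trace([(0, 0, 0), (1, 1, 0), (2, 0, 0)])
        axis = AxisLine(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        with pytest.warns(UserWarning):
            assert detect_2d_knot(trace, (1, 1), axis) is False


class TestFlagging:
    def test_knotted_loop_flags_its_strand(self, knotted_structure):
        chain = select_analysis_chain(knotted_structure)
        (sheet,) = knotted_structure.sheets
        flags = flag_knotted_strands(sheet, chain, knotted_structure.ca_coordinates,
                                     knotted_structure.helices)
        assert 2 in flags

    def test_plain_fixture_unflagged(self, open_structure):
        chain = select_analysis_chain(open_structure)
        (sheet,) = open_structure.sheets
        flags = flag_knotted_strands(sheet, chain, open_structure.ca_coordinates,
                                     open_structure.helices)
        assert flags == set()

    def test_flags_invariant_under_rigid_motion(self, knotted_structure):
        chain = select_analysis_chain(knotted_structure)
        (sheet,) = knotted_structure.sheets
        ref = flag_knotted_strands(sheet, chain, knotted_structure.ca_coordinates,
                                   knotted_structure.helices)
        moved = rotate(knotted_structure)
        got = flag_knotted_strands(sheet, chain, moved, knotted_structure.helices)
        assert got == ref


def test_projection_preserves_pairwise_distances_in_plane():
    axis = AxisLine(np.zeros(3), np.array([0.0, 0.0, 1.0]))
    trace = [((1, " "), np.array([0.0, 0.0, 3.0])), ((2, " "), np.array([3.0, 4.0, -7.0]))]
    proj = project_trace(trace, axis)
    assert np.linalg.norm(proj.points[1] - proj.points[0]) == pytest.approx(5.0)
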