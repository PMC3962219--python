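"""Two-dimensional knot detection on projected CA traces.

A "2D knot" is a crossing of the main chain seen in a flat projection of
the CA trace — not a topological knot in three dimensions.  Two viewing
axes are used, and a crossing in either view counts:

* the **sheet axis** — the line through one CA of the first registration
  strand and one CA of the last, chosen by brute force to minimize the
  summed per-strand (min over that strand's CAs) distances to the line;
* the **end-perpendicular axis** — through the CA at a strand's end,
  normal to the local sheet plane spanned by strand CAs at positions m and
  m+2 near that end and one paired CA in the adjacent strand.

The chain is projected onto the plane normal to the axis direction and a
crossing is a *proper* 2D intersection (strict transversal crossing, no
shared endpoints) between a segment of the connecting loop at the strand's
end and any non-adjacent segment of the projected chain trace.  The loop
runs from the strand end to the next secondary-structure element (a helix
or another strand of the same sheet), capped at 30 residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .pdbio import ChainRecord, SheetRecord, StrandRecord

__all__ = [
    "MAX_LOOP_RESIDUES",
    "AxisLine",
    "ProjectedTrace",
    "DegeneratePlaneError",
    "sheet_axis",
    "end_perpendicular_axis",
    "project_trace",
    "detect_2d_knot",
    "flag_knotted_strands",
]

#: Loops longer than this are not searched for crossings.
MAX_LOOP_RESIDUES = 30

_EPS = 1e-9

CaMap = Mapping[tuple[str, tuple[int, str]], np.ndarray]


class DegeneratePlaneError(ValueError):
    """The three plane-defining CAs are (nearly) collinear."""


@dataclass(frozen=True)
class AxisLine:
    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            if n < _EPS:
                raise ValueError("axis direction must be non-zero")
            object.__setattr__(self, "direction", d / n)
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))

    def distance(self, points: np.ndarray) -> np.ndarray:
        rel = np.atleast_2d(points) - self.point
        return np.linalg.norm(np.cross(rel, self.direction), axis=-1)


@dataclass(frozen=True)
class ProjectedTrace:
    points: np.ndarray  # (N, 2)
    residue_ids: tuple[tuple[int, str], ...]


def _strand_cas(
    strand: StrandRecord, ca_coordinates: CaMap
) -> list[tuple[tuple[int, str], np.ndarray]]:
    """Ordered (residue key, CA) pairs within the strand's author extent."""
    b, e = strand.begin_residue[0], strand.end_residue[0]
    hits = [
        (key, xyz)
        for (cid, key), xyz in ca_coordinates.items()
        if cid == strand.chain_id and b <= key[0] <= e
    ]
    hits.sort(key=lambda kv: kv[0])
    return hits


def sheet_axis(sheet: SheetRecord, ca_coordinates: CaMap) -> AxisLine:
    """Brute-force best line through one end-strand CA pair.

    Ties are broken deterministically toward the lowest residue numbers
    (candidates are visited in residue order; only a strict improvement
    replaces the incumbent).
    """
    per_strand = [_strand_cas(s, ca_coordinates) for s in sheet.strands]
    for strand, cas in zip(sheet.strands, per_strand):
        if not cas:
            raise ValueError(
                f"no CA coordinates for strand {strand.strand_ordinal} "
                f"of sheet {sheet.sheet_id}"
            )
    coords = [np.asarray([xyz for _, xyz in cas]) for cas in per_strand]
    best: tuple[float, AxisLine] | None = None
    for _, a in per_strand[0]:
        for _, b in per_strand[-1]:
            d = b - a
            if np.linalg.norm(d) < _EPS:
                continue
            axis = AxisLine(a, d)
            objective = sum(float(axis.distance(pts).min()) for pts in coords)
            if best is None or objective < best[0] - _EPS:
                best = (objective, axis)
    if best is None:
        raise ValueError(f"sheet {sheet.sheet_id}: degenerate end-strand coordinates")
    return best[1]


def end_perpendicular_axis(
    strand: StrandRecord,
    end: str,
    paired_ca: np.ndarray,
    ca_coordinates: CaMap,
) -> AxisLine:
    """Axis through the strand-end CA, normal to the local sheet plane.

    ``end`` is "N" or "C".  The plane is spanned by the strand CAs at the
    two positions m, m+2 closest to that end together with the paired CA
    of the adjacent strand.
    """
    cas = _strand_cas(strand, ca_coordinates)
    if len(cas) < 3:
        raise ValueError(
            f"strand {strand.strand_ordinal} needs >= 3 CAs near its end, has {len(cas)}"
        )
    if end == "N":
        end_ca, skip_ca = cas[0][1], cas[2][1]
    elif end == "C":
        end_ca, skip_ca = cas[-1][1], cas[-3][1]
    else:
        raise ValueError(f"end must be 'N' or 'C', got {end!r}")
    v1 = skip_ca - end_ca
    v2 = np.asarray(paired_ca, dtype=float) - end_ca
    normal = np.cross(v1, v2)
    n = np.linalg.norm(normal)
    if n < 1e-6:
        raise DegeneratePlaneError(
            f"collinear plane points at {end}-end of strand {strand.strand_ordinal}"
        )
    return AxisLine(end_ca, normal)


def _projection_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(d)))] = 1.0
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def project_trace(
    trace: Sequence[tuple[tuple[int, str], np.ndarray]], axis: AxisLine
) -> ProjectedTrace:
    """Project ordered CA positions onto the plane normal to the axis."""
    u, v = _projection_basis(axis.direction)
    pts = np.asarray([[xyz @ u, xyz @ v] for _, xyz in trace])
    return ProjectedTrace(points=pts, residue_ids=tuple(key for key, _ in trace))


def _proper_cross(p1, p2, q1, q2) -> bool:
    def orient(a, b, c) -> float:
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1 = orient(q1, q2, p1)
    d2 = orient(q1, q2, p2)
    d3 = orient(p1, p2, q1)
    d4 = orient(p1, p2, q2)
    eps = _EPS * max(1.0, abs(d1), abs(d2), abs(d3), abs(d4))
    return (d1 * d2 < -eps) and (d3 * d4 < -eps)


def detect_2d_knot(
    trace: Sequence[tuple[tuple[int, str], np.ndarray]],
    loop_range: tuple[int, int],
    axis: AxisLine,
) -> bool:
    """True iff a projected loop segment properly crosses a non-adjacent
    segment of the projected chain trace.

    ``loop_range`` gives the loop's (first, last) indices into ``trace``.
    Loops of fewer than two residues have no segments and return False.
    """
    lo, hi = loop_range
    if hi - lo < 1:
        warnings.warn("loop shorter than 2 residues: no segments to test")
        return False
    proj = project_trace(trace, axis).points
    n = len(proj)
    for t in range(lo, hi):  # loop segments t..t+1
        for u in range(n - 1):  # chain segments u..u+1
            if abs(t - u) <= 1:
                continue
            if _proper_cross(proj[t], proj[t + 1], proj[u], proj[u + 1]):
                return True
    return False


def _chain_trace(
    chain: ChainRecord, ca_coordinates: CaMap
) -> list[tuple[tuple[int, str], np.ndarray]]:
    trace = [
        (key, xyz) for (cid, key), xyz in ca_coordinates.items() if cid == chain.chain_id
    ]
    trace.sort(key=lambda kv: kv[0])
    return trace


def _sse_bounds(sheet: SheetRecord, helices, chain_id: str) -> list[tuple[int, int]]:
    bounds = [(s.begin_residue[0], s.end_residue[0]) for s in sheet.strands]
    bounds += [(b[0], e[0]) for cid, b, e in helices if cid == chain_id]
    return sorted(bounds)


def _loop_after(end_num: int, bounds, trace_nums) -> tuple[int, int] | None:
    nxt = [b for b, _ in bounds if b > end_num]
    if not nxt:
        return None
    stop = min(nxt)
    lo = end_num + 1
    hi = stop - 1
    if hi - lo + 1 > MAX_LOOP_RESIDUES or hi < lo:
        return None
    try:
        return trace_nums.index(lo), trace_nums.index(hi)
    except ValueError:
        return None


def _loop_before(begin_num: int, bounds, trace_nums) -> tuple[int, int] | None:
    prev = [e for _, e in bounds if e < begin_num]
    if not prev:
        return None
    stop = max(prev)
    lo = stop + 1
    hi = begin_num - 1
    if hi - lo + 1 > MAX_LOOP_RESIDUES or hi < lo:
        return None
    try:
        return trace_nums.index(lo), trace_nums.index(hi)
    except ValueError:
        return None


def flag_knotted_strands(
    sheet: SheetRecord,
    chain: ChainRecord,
    ca_coordinates: CaMap,
    helices: Sequence[tuple[str, tuple[int, str], tuple[int, str]]] = (),
) -> set[int]:
    """Ordinals of strands with a 2D-knotted connecting loop at either end.

    A strand is flagged when the loop from one of its ends to the next
    secondary-structure element crosses the chain trace in the sheet-axis
    view or in that end's perpendicular-axis view.  Per-strand geometric
    failures downgrade to warnings (strand left unflagged).
    """
    trace = _chain_trace(chain, ca_coordinates)
    if len(trace) < 3:
        return set()
    trace_nums = [key[0] for key, _ in trace]
    bounds = _sse_bounds(sheet, helices, chain.chain_id)
    try:
        axis0 = sheet_axis(sheet, ca_coordinates)
    except ValueError as err:
        warnings.warn(f"sheet axis unavailable: {err}")
        axis0 = None

    flagged: set[int] = set()
    for pos, strand in enumerate(sheet.strands):
        for end in ("N", "C"):
            if end == "N":
                loop = _loop_before(strand.begin_residue[0], bounds, trace_nums)
            else:
                loop = _loop_after(strand.end_residue[0], bounds, trace_nums)
            if loop is None:
                continue
            axes: list[AxisLine] = [] if axis0 is None else [axis0]
            try:
                paired = _paired_ca(sheet, pos, end, ca_coordinates)
                axes.append(end_perpendicular_axis(strand, end, paired, ca_coordinates))
            except (ValueError, DegeneratePlaneError) as err:
                warnings.warn(
                    f"perpendicular axis unavailable for strand "
                    f"{strand.strand_ordinal} ({end}-end): {err}"
                )
            if any(detect_2d_knot(trace, loop, axis) for axis in axes):
                flagged.add(strand.strand_ordinal)
                break
    return flagged


def _paired_ca(sheet: SheetRecord, pos: int, end: str, ca_coordinates: CaMap) -> np.ndarray:
    """Nearest CA in the neighbouring registration strand to this strand's end CA."""
    strand = sheet.strands[pos]
    neighbours = [p for p in (pos - 1, pos + 1) if 0 <= p < len(sheet.strands)]
    cas = _strand_cas(strand, ca_coordinates)
    if not cas:
        raise ValueError(f"no CAs for strand {strand.strand_ordinal}")
    end_ca = cas[0][1] if end == "N" else cas[-1][1]
    best: tuple[float, np.ndarray] | None = None
    for p in neighbours:
        for _, xyz in _strand_cas(sheet.strands[p], ca_coordinates):
            d = float(np.linalg.norm(xyz - end_ca))
            if best is None or d < best[0]:
                best = (d, xyz)
    if best is None:
        raise ValueError(
            f"no paired CA in strands adjacent to strand {strand.strand_ordinal}"
        )
    return best[1]
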