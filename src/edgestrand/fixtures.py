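"""Deterministic synthetic PDB entries with designed SOF coverage.

Every pipeline stage can be exercised without downloading anything: a
:class:`SheetSpec` describes a small single-chain entry containing one
beta-sheet (>= 2 strands), and :func:`make_structure` renders it as PDB
text with DBREF, SEQRES, SHEET, optional HELIX, and CA-only ATOM records.
Generation is a pure function of the spec: the same spec yields
byte-identical text.

Sequences are *designed*, not random: each strand carries a target
coverage class realised from a small residue palette —

* ``zero`` — poly-glycine; no gly-run of 2..21 residues has a square mass,
  so the strand carries no SOF coverage at all;
* ``low``  — proline filler with one central ASP-ARG pair (mass
  115+156+18 = 289 = 17**2), giving 0 < V_m < 0.34 for lengths >= 6;
* ``mid``  — ASP-ARG pairs spaced by prolines, giving V_m around 0.4-0.8;
* ``high`` — alternating ASP/ARG, where every adjacent pair is a square,
  giving V_m well above 1.

Because SOF intervals reach across strand/loop boundaries, the composed
chain is verified by full enumeration and deterministically repaired
(loop/tail residues mutated) until every strand meets its class
constraint; an unreachable design raises :class:`GenerationError`.

Geometry is an idealised antiparallel sheet: strands along x with 3.4 A
CA steps, 4.8 A strand spacing, loops arcing out of plane.  ``barrel``
wraps the strands on a cylinder so the first and last strands touch.
``knotted_loops`` re-routes the named loops through the sheet's interior
with a dip through the sheet plane, creating a crossing in the sheet-axis
projection.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .masses import DEFAULT_TABLE
from .sof import coverage_profile, enumerate_sof

__all__ = ["SheetSpec", "GenerationError", "design_sequence", "make_structure"]

CA_STEP = 3.4  # A between consecutive CAs along a strand
STRAND_SPACING = 4.8  # A between adjacent strands
LOOP_ARC_HEIGHT = 3.0  # A out-of-plane arc of a regular loop

_FILLER_ALPHABET = ("ALA", "SER", "PRO", "VAL", "THR", "LEU", "ASN", "GLN", "LYS", "GLU")
_CLASSES = ("zero", "low", "mid", "high")


class GenerationError(RuntimeError):
    """The spec cannot be realised (contradictory or design search failed)."""


@dataclass(frozen=True)
class SheetSpec:
    n_strands: int = 4
    residues_per_strand: int | Sequence[int] = 6
    loop_lengths: int | Sequence[int] = 4
    sequence_plan: Sequence[str] | None = None  # per-strand coverage class
    barrel: bool = False
    knotted_loops: frozenset[int] = frozenset()  # loop i joins strand i and i+1 (1-based)
    tail_helix: bool = False
    author_offset: int = 0
    chain_id: str = "A"
    entry_id: str = "SYN1"
    seed: int = 0

    def strand_lengths(self) -> list[int]:
        r = self.residues_per_strand
        lengths = [r] * self.n_strands if isinstance(r, int) else list(r)
        if len(lengths) != self.n_strands:
            raise GenerationError("residues_per_strand length != n_strands")
        return lengths

    def loop_lens(self) -> list[int]:
        ll = self.loop_lengths
        loops = [ll] * (self.n_strands - 1) if isinstance(ll, int) else list(ll)
        if len(loops) != self.n_strands - 1:
            raise GenerationError("loop_lengths must have n_strands - 1 entries")
        return loops

    def plan(self) -> list[str]:
        plan = ["zero"] * self.n_strands if self.sequence_plan is None else list(self.sequence_plan)
        if len(plan) != self.n_strands:
            raise GenerationError("sequence_plan length != n_strands")
        for cls in plan:
            if cls not in _CLASSES:
                raise GenerationError(f"unknown coverage class {cls!r}")
        return plan

    @classmethod
    def from_json(cls, text: str) -> "SheetSpec":
        data = json.loads(text)
        if "knotted_loops" in data:
            data["knotted_loops"] = frozenset(data["knotted_loops"])
        return cls(**data)


def design_sequence(plan: str, length: int, verify: bool = True) -> list[str]:
    """A strand sequence realising one coverage class in isolation."""
    if length < 4:
        raise GenerationError("strands need >= 4 residues")
    if plan == "zero":
        seq = ["GLY"] * length
    elif plan == "low":
        if length < 6:
            raise GenerationError("'low' strands need >= 6 residues (2/L < 0.34)")
        mid = (length - 2) // 2
        seq = ["PRO"] * mid + ["ASP", "ARG"] + ["PRO"] * (length - mid - 2)
    elif plan == "mid":
        # evenly spaced ASP-ARG pairs among prolines: V_m ~ 2p / length
        pairs = max(1, -(-length // 5))
        seq = ["PRO"] * length
        for b in range(pairs):
            start = round(b * length / pairs)
            seq[start : start + 2] = ["ASP", "ARG"]
    elif plan == "high":
        seq = [("ASP", "ARG")[i % 2] for i in range(length)]
    else:
        raise GenerationError(f"unknown coverage class {plan!r}")
    if verify and not _class_ok(plan, _strand_vm(seq, 0, length)):
        raise GenerationError(f"designed {plan!r} strand of length {length} failed verification")
    return seq


def _strand_vm(sequence: Sequence[str], start: int, length: int) -> tuple[float, list[int]]:
    profile = coverage_profile(len(sequence), enumerate_sof(sequence, table=DEFAULT_TABLE))
    window = [profile[p] for p in range(start + 1, start + length + 1)]
    return sum(window) / length, window


def _class_ok(plan: str, vm_window: tuple[float, list[int]]) -> bool:
    vm, window = vm_window
    if plan == "zero":
        return all(v == 0 for v in window)
    if plan == "low":
        return 0 < vm < 0.34
    if plan == "mid":
        return 0.34 <= vm < 1.5
    if plan == "high":
        return vm >= 1.5
    raise GenerationError(plan)


def _compose_sequence(spec: SheetSpec, rng: random.Random) -> tuple[list[str], list[tuple[int, int]]]:
    """Full chain sequence plus 0-based [start, end) extents of each strand."""
    lengths = spec.strand_lengths()
    loops = spec.loop_lens()
    plan = spec.plan()
    seq: list[str] = []
    extents: list[tuple[int, int]] = []
    for i, (length, cls) in enumerate(zip(lengths, plan)):
        start = len(seq)
        seq += design_sequence(cls, length, verify=False)
        extents.append((start, start + length))
        if i < len(loops):
            seq += ["GLY"] * loops[i]
    if len(seq) < 50 or spec.tail_helix:
        tail = max(50 - len(seq), 8 if spec.tail_helix else 0)
        seq += ["GLY"] * tail

    # verify-and-repair: mutate loop/tail residues until every strand class holds
    strand_pos = {p for b, e in extents for p in range(b, e)}
    mutable = [p for p in range(len(seq)) if p not in strand_pos]
    for _attempt in range(1000):
        sof = enumerate_sof(seq, table=DEFAULT_TABLE)
        profile = coverage_profile(len(seq), sof)
        bad = None
        for (b, e), cls in zip(extents, plan):
            window = [profile[p] for p in range(b + 1, e + 1)]
            if not _class_ok(cls, (sum(window) / len(window), window)):
                bad = (b, e, cls)
                break
        if bad is None:
            return seq, extents
        b, e, _cls = bad
        # mutate a mutable residue inside an SOF interval that intrudes on the strand
        intruding = [iv for iv in sof if iv.start - 1 < e and iv.end > b]
        mutable_set = set(mutable)
        candidates = sorted(
            {
                p
                for iv in intruding
                for p in range(iv.start - 1, iv.end)
                if p in mutable_set
            }
        )
        if not candidates:
            candidates = mutable
        pos = rng.choice(candidates)
        current = seq[pos]
        seq[pos] = rng.choice([a for a in _FILLER_ALPHABET if a != current])
    raise GenerationError("could not satisfy strand coverage classes in 1000 attempts")


def _open_sheet_coords(spec: SheetSpec, extents, total: int) -> np.ndarray:
    lengths = spec.strand_lengths()
    loops = spec.loop_lens()
    xmax = (max(lengths) - 1) * CA_STEP
    coords = np.zeros((total, 3))
    ends = []
    for r, (b, e) in enumerate(extents):
        n = e - b
        forward = r % 2 == 0
        for k in range(n):
            x = k * CA_STEP if forward else (n - 1 - k) * CA_STEP
            coords[b + k] = (x, r * STRAND_SPACING, 0.0)
        ends.append((coords[b], coords[e - 1]))
    # loops
    for r in range(len(loops)):
        lo = extents[r][1]
        hi = extents[r + 1][0]
        n = hi - lo
        p0 = coords[extents[r][1] - 1]
        p1 = coords[extents[r + 1][0]]
        knotted = (r + 1) in spec.knotted_loops
        for k in range(n):
            t = (k + 1) / (n + 1)
            if knotted:
                # wander over the sheet interior and dip through its plane:
                # crossing z = 0 inside the strands' x-range crosses the
                # projected chain in the sheet-axis (x-z) view.
                x = xmax * (0.75 - 0.5 * t)
                y = p0[1] + (p1[1] - p0[1]) * t
                z = 2.5 if t < 0.45 else (-2.5 if t < 0.8 else 1.5)
                coords[lo + k] = (x, y, z)
            else:
                coords[lo + k] = (
                    p0[0] + (p1[0] - p0[0]) * t,
                    p0[1] + (p1[1] - p0[1]) * t,
                    LOOP_ARC_HEIGHT * np.sin(np.pi * t),
                )
    # tail: straight line leaving the sheet in +y
    tail_start = extents[-1][1]
    origin = coords[tail_start - 1]
    for k in range(tail_start, total):
        coords[k] = origin + np.array([0.0, (k - tail_start + 1) * CA_STEP, 0.0])
    return coords


def _barrel_coords(spec: SheetSpec, extents, total: int) -> np.ndarray:
    n_strands = spec.n_strands
    radius = STRAND_SPACING / (2 * np.sin(np.pi / n_strands))
    coords = np.zeros((total, 3))
    angles = [2 * np.pi * r / n_strands for r in range(n_strands)]
    for r, (b, e) in enumerate(extents):
        n = e - b
        forward = r % 2 == 0
        for k in range(n):
            x = k * CA_STEP if forward else (n - 1 - k) * CA_STEP
            coords[b + k] = (x, radius * np.cos(angles[r]), radius * np.sin(angles[r]))
    for r in range(n_strands - 1):
        lo, hi = extents[r][1], extents[r + 1][0]
        p0, p1 = coords[lo - 1], coords[hi]
        a0, a1 = angles[r], angles[r + 1]
        n = hi - lo
        for k in range(n):
            t = (k + 1) / (n + 1)
            a = a0 + (a1 - a0) * t
            rr = radius + 2.0
            coords[lo + k] = (p0[0] + (p1[0] - p0[0]) * t, rr * np.cos(a), rr * np.sin(a))
    tail_start = extents[-1][1]
    origin = coords[tail_start - 1]
    for k in range(tail_start, total):
        coords[k] = origin + np.array([(k - tail_start + 1) * CA_STEP, 0.0, 0.0])
    return coords


def make_structure(spec: SheetSpec) -> str:
    """Render the spec as PDB-format text (DBREF/SEQRES/SHEET/HELIX/ATOM)."""
    if spec.n_strands < 2:
        raise GenerationError("a sheet needs >= 2 strands")
    if spec.barrel and spec.n_strands < 3:
        raise GenerationError("a barrel needs >= 3 strands")
    if spec.barrel and spec.knotted_loops:
        raise GenerationError("knotted loops are only supported for open sheets")
    for loop_idx in spec.knotted_loops:
        if not 1 <= loop_idx <= spec.n_strands - 1:
            raise GenerationError(f"knotted loop index {loop_idx} out of range")
        if spec.loop_lens()[loop_idx - 1] < 4:
            raise GenerationError("knotted loops need length >= 4")

    rng = random.Random(spec.seed)
    seq, extents = _compose_sequence(spec, rng)
    total = len(seq)
    coords = (_barrel_coords if spec.barrel else _open_sheet_coords)(spec, extents, total)

    ch = spec.chain_id
    off = spec.author_offset
    lines = [f"HEADER    SYNTHETIC SHEET FIXTURE                 01-JAN-00   {spec.entry_id:<4s}"]
    lines.append(
        f"DBREF  {spec.entry_id:<4s} {ch} {1 + off:>4d}  {total + off:>4d}  "
        f"UNP    P99999   SYNTH_TEST      {1:>5d}  {total:>5d}"
    )
    for i in range(0, total, 13):
        block = " ".join(f"{c:>3s}" for c in seq[i : i + 13])
        lines.append(f"SEQRES {i // 13 + 1:>3d} {ch} {total:>4d}  {block}")
    if spec.tail_helix:
        hb = extents[-1][1] + 2 + off  # a short helix in the tail bounds the last loop
        he = hb + 3
        lines.append(
            f"HELIX    1   1 {seq[hb - 1 - off]:>3s} {ch} {hb:>4d}  "
            f"{seq[he - 1 - off]:>3s} {ch} {he:>4d}  1{'':30s}{4:>6d}"
        )
    n_str = spec.n_strands
    for r, (b, e) in enumerate(extents):
        sense = 0 if r == 0 else -1
        lines.append(
            f"SHEET  {r + 1:>3d} SHA{n_str:>2d} {seq[b]:>3s} {ch}{b + 1 + off:>4d} "
            f" {seq[e - 1]:>3s} {ch}{e + off:>4d} {sense:>2d}"
        )
    for i, (code, xyz) in enumerate(zip(seq, coords), start=1):
        lines.append(
            f"ATOM  {i:>5d}  CA  {code:>3s} {ch}{i + off:>4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
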