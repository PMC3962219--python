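# Methods

## Mass model

Residue masses are integer nucleon counts computed from in-chain molecular
formulas with mass numbers H=1, C=12, N=14, O=16, S=32 (`masses.py` stores
the formulas and derives the table; tests recompute it independently).
Two deliberate conventions:

* **Selenium counts as sulfur.** Selenomethionine (MSE) is an engineered
  stand-in for methionine in crystallography; giving Se the S mass number
  makes MSE and MET score identically (131) and keeps engineered entries
  comparable to native ones.
* **Free peptides include one water** (+18 for the terminal H and OH).
  The convention is observable: free cysteine is then 121 = 11², the
  unique square-mass single residue, which is exactly why span-0 intervals
  are excluded from SOF enumeration. Under the dry convention no single
  residue is square and the exclusion would be vacuous. The switch
  (`ResidueMassTable(with_water=False)`) is exposed for comparison.

All arithmetic is exact integer arithmetic; the largest possible interval
mass (21 × 186 + 18 = 3924) is far below any overflow concern, and square
testing uses `math.isqrt`, never floating point.

## SOF enumeration

An SOF is an interval `[i, j]`, 1-based inclusive, with span
`j − i ∈ [min_span, max_span]` and square peptide mass. Defaults are
spans 1–20 (peptides of 2–21 residues): span 0 would admit only the
single-cysteine SOF, which is excluded by design, and the upper bound
follows the mutational-robustness argument that long SOFs are fragile.
The program text describing the original enumeration is ambiguous between
"up to 20 residues" and "up to span 20"; both bounds are constructor
arguments, and the default (span ≤ 20) was fixed once against the worked
example below. `V(p)` is plain interval coverage — the number of SOFs
containing `p` — computed by a difference-array sweep; the alternative
"SOFs starting at p" reading produces per-strand means an order of
magnitude below the worked example's printed values and was rejected.

Residues without a defined mass (UNK, unmodelled chemistry) poison only
the intervals that contain them: those intervals are skipped and counted
in a `SkipReport`, and coverage elsewhere is unaffected. Treating unknown
residues as mass 0 would silently create spurious squares.

## Entry handling

PDB parsing is delegated to gemmi (SEQRES, SHEET, HELIX, first-MODEL CA
coordinates, polymer typing); DBREF chain order is scanned from the raw
record text because gemmi does not surface DBREF. Entry policy: nucleic
chains are not analyzable, chains under 50 residues are peptides, and the
analysis chain is the first protein chain of ≥ 50 residues in DBREF order
(SEQRES order as fallback). SEQRES indices are 1-based everywhere in the
library; author numbering exists only at the I/O boundary, mapped
arithmetically from the DBREF begin number, or by ordered occurrence when
insertion codes are present. A CA count below the SEQRES length flags
missing residues but never excludes an entry. Strands whose extents
cannot be mapped are dropped per-strand with a warning rather than
failing the entry; sheets are then re-checked for eligibility.

## Scoring and prediction

Strands of ≤ 3 residues are ignored; a sheet is scored when ≥ 4 strands
survive (the stricter of the two possible filter orders; the
declared-count basis is available as `basis="declared"`). `V_m` is the
arithmetic mean of V over the strand's SEQRES positions. The rule:
minimum `V_m` predicts an edge when it lies in [0, 0.34) — the bound is
strict at 0.34 — otherwise the maximum predicts an edge. Exactly one
branch fires per sheet, and one prediction (one edge, not both) is made
per sheet, which is what the binomial evaluation counts as an assay.

Ties at the extreme are reported in full (`tie_policy="report-all"`), and
evaluation counts the first tied strand in registration order; the paper
trail for every sheet includes all `V_m` values so a different tie policy
can be audited after the fact.

Ground truth: the first and last strands in SHEET-record registration
order of an open sheet. Barrels have no edges; a sheet is called closed
when the minimum CA–CA distance between its first and last registration
strands is below 5.5 Å — roughly the inter-strand spacing (≈ 4.8 Å) plus
slack — and closed sheets are excluded. When coordinates are absent the
sheet is treated as open (declared topology).

## 2D-knot exclusion (improved rule)

The improved rule removes from candidacy any strand whose connecting loop
is "knotted" in a flat projection, then applies the unchanged base rule.
Operational definitions, chosen once and isolated behind single
predicates:

* **Sheet axis**: brute force over pairs (CA of first strand, CA of last
  strand), minimizing the sum over strands of the minimal CA-to-line
  distance; deterministic tie-break toward lower residue numbers. On
  idealised lattice-like sheets multiple zero-objective lines can exist;
  any of them is a valid viewing axis.
* **End-perpendicular axis**: through the strand-end CA, normal to the
  plane of strand CAs m, m+2 nearest that end and the closest CA of an
  adjacent registration strand; near-collinear planes raise a degenerate
  error and downgrade to a warning at the batch level.
* **Crossing**: a *proper* 2D segment–segment intersection (strict
  transversal crossing, shared endpoints and collinear overlaps excluded)
  between a segment of the projected loop and any non-adjacent segment of
  the projected CA trace. The loop runs from the strand end to the next
  secondary-structure element (helix or strand of the same sheet), capped
  at 30 residues; either axis view suffices to flag.

The knot test is a heuristic reading of a figure-defined construct, so it
is off by default (`use_knot_exclusion=False`, CLI `--base`) and the
deterministic core never depends on it.

## Exact binomial test

`p = Σ_{i=0..k} C(n, i) / 2ⁿ` with integer binomial coefficients and one
final rational division — no incomplete-beta shortcut, so printed bounds
can be checked without tolerance arguments. The 0.5 failure probability
is exact only for 4-stranded sheets and conservative for larger ones.
scipy's binomial CDF is used in tests as an independent cross-check, never
as the implementation.

## Synthetic fixtures

`fixtures.make_structure` renders a single-chain entry with one sheet as
CA-only PDB text; generation is a pure function of the `SheetSpec`.
Sequences realise per-strand coverage classes from a small palette:
poly-Gly ("zero": no glycine run of 2–21 residues is square), proline
filler with one central Asp-Arg pair ("low": 289 = 17² covering two
residues, `V_m = 2/L < 0.34`), evenly spaced Asp-Arg pairs ("mid",
`V_m ≈ 0.4–0.8`), and alternating Asp/Arg ("high": every adjacent pair is
square, `V_m > 1.5`). Because SOFs reach across boundaries, the composed
chain is verified by full enumeration and repaired by deterministically
mutating loop/tail residues (bounded at 1000 attempts).

Geometry is an idealised antiparallel sheet (3.4 Å CA steps, 4.8 Å strand
spacing, planar strands, out-of-plane loop arcs, ≥ 50 residues total);
`barrel=True` wraps strands on a cylinder whose first/last gap equals the
strand spacing, and `knotted_loops` re-routes a loop over the sheet
interior with a dip through the sheet plane, which crosses the projected
trace in the sheet-axis view. These fixtures emulate the *topology* the
method consumes — SHEET registration order, strand extents, CA traces,
numbering offsets — not real backbone dihedrals, hydrogen bonding, or the
coverage statistics of natural sequences. Passing the fixture suite
therefore demonstrates that the machinery implements the stated rules
exactly, not that the rules achieve any particular accuracy on real
structures (that evaluation needs curated PDB test sets).

## The transthyretin stand-in

The worked example ships as a synthetic reconstruction
(`reference.py`): the canonical mature human transthyretin sequence
(127 residues) plus the two sheets' strand extents and edge/central
labels in registration order. All sixteen strand-boundary residues match
this sequence at their stated positions. Deposited transthyretin entries
from the early crystallographic literature differ from the modern
reference sequence at a few positions, so per-strand `V_m` values
computed here can differ in the first decimal from table values derived
from one specific deposited entry; the per-sheet `V_m` *ranking* and both
predicted edge strands are reproduced exactly, and were used (together
with the single-cysteine argument) to fix the mass and span conventions.

## Problem sizes

The test suite and the acceptance script are sized for a laptop-class
run: 100 random 30-residue chains for oracle equivalence, the full
(n ≤ 100) binomial grid, and a 20-entry synthetic batch for rule
recovery. Everything completes in seconds.

## Known limitations

* One chain per entry (the first DBREF protein chain); sheets spanning
  several chains are scored only on strands of the analysis chain.
* The knot detector's crossing scope is loop-vs-whole-trace; the
  original construct is defined only by figures, and other scopes
  (loop-vs-itself, loop-vs-sheet-neighbourhood) are plausible readings.
* Ground truth equates registration order with spatial order, which is
  how SHEET records are written but is not re-derived from hydrogen
  bonding.
* `mmCIF` input is not supported; PDB-format text only.
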