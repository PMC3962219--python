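# edgestrand

Prediction of **edge strands** in protein beta-sheets from sequence alone,
using perfect-square peptide-mass scoring, with an exact binomial
significance test and a geometric "2D-knot" exclusion rule.

## The problem

Every strand of an open beta-sheet is hydrogen-bonded to two neighbours,
except the two *edge strands*, which pair with only one. Knowing which
strand sits at the edge is topological information about the fold that is
useful for model quality checks and structure prediction, and edge strands
are also where sheets aggregate. This package implements a sequence-based
rule for picking one edge strand per sheet, plus the machinery to evaluate
it on structures (PDB SHEET annotations provide the ground truth).

## The method

For a chain of `L` residues, every sub-sequence `S(i, j)` with span
`j − i ∈ [1, 20]` (2 to 21 residues) is assigned an integer **nucleon
mass**: each atom counts its mass number (H=1, C=12, N=14, O=16, S=32;
Se is counted as S so selenomethionine scores as methionine), and a free
peptide includes one water for its termini. If the mass `M` is a perfect
square — `√M = ⌊√M⌋`, checked with exact integer arithmetic — the
sub-sequence is an **SOF** ("sequence optimized for folding"). Single
residues are excluded; the only residue whose free mass is square is
cysteine (103 + 18 = 121 = 11²).

`V(p)` counts the SOFs covering position `p`, and a strand's score is the
mean `V_m` over its residues. The prediction rule per sheet (strands of
≥ 4 residues, sheets with ≥ 4 such strands, barrels excluded):

* **low branch** — if some strand has `0 ≤ V_m < 0.34`, the minimal `V_m`
  marks an edge strand;
* **high branch** — otherwise the maximal `V_m` marks an edge strand.

The **improved rule** first removes strands whose connecting loop crosses
the projected CA trace (a *2D knot*, tested along the sheet axis and along
the strand-end perpendicular axis), then applies the same rule to the rest.

A batch of predictions (one assay per sheet) is scored against the
registration-order endpoints of the SHEET records; significance is the
exact fair-coin tail `p = Σ_{i≤k} C(n, i) / 2ⁿ`, a conservative bound
because sheets of more than four strands have a failure probability below
one half.

## Worked example

`python examples/transthyretin_example.py` scores the bundled stand-in of
human transthyretin (a beta-sandwich of two 4-stranded sheets; edge
strands labelled E, central C):

```
sheet A:
  strand  115-123  E1  V_m = 1.22
  strand  103-112  C1  V_m = 1.30
  strand    11-18  C2  V_m = 2.25
  strand    53-56  E2  V_m = 4.75 <- predicted edge
  high branch of the base rule; the predicted strand is an edge

sheet B:
  strand    45-49  E1  V_m = 4.20 <- predicted edge
  strand    28-36  C1  V_m = 3.44
  strand    66-74  C2  V_m = 3.11
  strand    90-97  E2  V_m = 2.25
  high branch of the base rule; the predicted strand is an edge
```

No `V_m` falls below 0.34, so the high branch fires in both sheets and the
maximal-`V_m` strand is predicted; in both sheets it is a genuine edge
strand. `examples/predict_edges.py` shows the improved rule rescuing a
sheet whose central strand carries the extreme `V_m` but is tied into a 2D
knot, and `examples/significance.py` prints the exact binomial p-values
for batches of 96 and 92 assays.

## Command line

```bash
edgestrand fixture --out toy.pdb          # synthetic test entry
edgestrand sof toy.pdb                    # SOF intervals + per-residue V
edgestrand score toy.pdb                  # per-strand V_m table
edgestrand predict toy.pdb --improved     # per-sheet edge predictions
edgestrand evaluate predictions.tsv       # n, k, accuracy, exact p
```

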