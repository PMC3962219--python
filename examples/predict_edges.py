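"""Edge-strand prediction on a synthetic 4-strand sheet.

Builds an idealised antiparallel sheet whose second strand is designed to
carry dominant SOF coverage, runs the pipeline, and shows that the base
rule picks the V_m extreme while the improved rule can veto a strand whose
connecting loop forms a 2D knot.
"""

from edgestrand.fixtures import SheetSpec, make_structure
from edgestrand.pipeline import analyze_entry
from edgestrand.predict import PredictionConfig

spec = SheetSpec(sequence_plan=["mid", "high", "mid", "mid"], knotted_loops=frozenset({2}))
text = make_structure(spec)

base = analyze_entry(text).sheets[0]
improved = analyze_entry(text, PredictionConfig(use_knot_exclusion=True)).sheets[0]

print("V_m by strand:", {o: round(v, 2) for o, v in base.prediction.v_m_by_ordinal.items()})
print("true edges (registration endpoints):", sorted(base.true_edges))
print("base rule predicts strand", base.prediction.predicted_strand_ordinals,
      "->", "correct" if base.correct else "wrong (central strand with extreme V_m)")
print("improved rule excludes", improved.prediction.excluded_ordinals,
      "and predicts", improved.prediction.predicted_strand_ordinals,
      "->", "correct" if improved.correct else "wrong")
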