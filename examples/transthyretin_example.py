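"""The transthyretin worked example.

Human transthyretin is a beta-sandwich of two four-stranded sheets.  The
stand-in entry bundled with the package (canonical mature sequence plus
the two sheets' strand extents) is scored and one edge strand per sheet is
predicted from sequence alone.
"""

from edgestrand.reference import run_reference

res = run_reference()
for sheet_id, info in res["sheets"].items():
    print(f"sheet {sheet_id}:")
    for extent, vm in info["v_m"].items():
        label = info["labels"][extent]
        mark = " <- predicted edge" if extent == info["predicted_extent"] else ""
        print(f"  strand {extent:>8}  {label}  V_m = {vm:.2f}{mark}")
    ok = "an edge" if info["predicted_is_edge"] else "NOT an edge"
    print(f"  high branch of the base rule; the predicted strand is {ok}\n")
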