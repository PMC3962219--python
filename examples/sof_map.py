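"""SOF enumeration for a plain sequence.

Every contiguous sub-peptide of 2-21 residues whose nucleon mass is a
perfect square is an SOF; V counts how many SOFs cover each residue.
"""

from edgestrand.sof import coverage_profile, enumerate_sof, sequence_from_text

seq = sequence_from_text("DRGHTPWKCLMDRA")  # 1-letter input
intervals = enumerate_sof(seq)
profile = coverage_profile(len(seq), intervals)

print("intervals (start, end, mass):")
for iv in intervals:
    print(f"  {iv.start:>3} {iv.end:>3}  mass {iv.mass} = {int(iv.mass ** 0.5)}^2")
print("per-residue coverage V:", list(profile.values))
# Each interval is a square-mass peptide; residues under many intervals get
# high V, and strand means of V (V_m) are what the edge rule compares.
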