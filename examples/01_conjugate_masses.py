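"""Predict conjugate masses from an aglycone formula.

Given liquiritigenin (the licorice aglycone, C15H12O4), the default
biotransformation table predicts the neutral monoisotopic masses of its
phase-II conjugates.  These are the masses a mass-difference search looks
for among the detected peaks.
"""
from dacmet import default_reaction_table, monoisotopic_mass

aglycone = monoisotopic_mass("C15H12O4")
print(f"liquiritigenin            {aglycone:10.5f} Da")

deltas = {r.name: r.delta_mass for r in default_reaction_table()}
for reaction in ("sulfation", "glucuronidation"):
    mass = aglycone + deltas[reaction]
    print(f"  + {reaction:<22s}{mass:10.5f} Da  (nominal {round(mass)})")
both = aglycone + deltas["sulfation"] + deltas["glucuronidation"]
print(f"  + both conjugations     {both:10.5f} Da  (nominal {round(both)})")
# The three nominal masses (336, 432, 512 Da) are the peaks a conjugate
# network should connect back to the 256 Da aglycone.
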