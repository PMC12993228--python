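"""Consolidate the two reference 3x3 matrices into control categories.

The matrices carry the published cell counts of a six-pharmacy annual
assortment (10,541 products); folding them through the default
cell-to-category mapping reproduces the known category totals.
"""

from pharmstock import consolidate, make_fixture_matrices

medical, non_medical = make_fixture_matrices()

print("medical ABC x FSN matrix (cell counts):")
print(medical.to_frame(), "\n")
cats = consolidate(medical)
print("medical categories:", {k: v[0] for k, v in cats.items()})

print("\nnon-medical ABC x HML-P matrix (cell counts):")
print(non_medical.to_frame(), "\n")
cats = consolidate(non_medical)
print("non-medical categories:", {k: v[0] for k, v in cats.items()})

print()
print("Row A (top 70% of spend) and column F/H (fast-moving / high-profit)")
print("map to Category I (strict control); the CN/CL corner is Category III —")
print("low-value dead stock. Everything else is Category II.")
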