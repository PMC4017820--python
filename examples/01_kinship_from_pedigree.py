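"""Kinship coefficients from a small pedigree.

Builds one three-generation family (two founder grandparents, two
children with unrelated spouses, one grandchild each), computes the
kinship matrix by the recursive tabular method, and prints the classical
coefficients.  Kinship Phi_ij is the probability that two gene copies
drawn at random, one from each individual, are identical by descent;
2 * Phi scales the additive genetic covariance between relatives.
"""

from pedherit import build_three_generation_pedigree, kinship_matrix

ped = build_three_generation_pedigree(1)
k = kinship_matrix(ped)
df = k.to_dataframe()

print(df.round(4).to_string())
print()
for a, b, label in [
    ("F001_GP1", "F001_GP2", "unrelated founders"),
    ("F001_GP1", "F001_C1", "parent-offspring"),
    ("F001_C1", "F001_C2", "full siblings"),
    ("F001_GP1", "F001_G1", "grandparent-grandchild"),
    ("F001_G1", "F001_G2", "first cousins"),
]:
    print(f"Phi({label}) = {df.loc[a, b]:.4f}")
# 0.25 for parent-offspring means a trait covariance of 0.5 * sigma_A^2.
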