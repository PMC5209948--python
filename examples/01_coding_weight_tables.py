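"""How the marker coding fixes the epistasis effect model.

In a model whose interaction covariates are products of marker values, the
numbers chosen to encode the genotypes aa/aA/AA implicitly assign a weight to
every two-locus genotype combination: the combination (r, s) receives
coding[r] * coding[s] times the pair's interaction effect.  This script prints
those weight tables for the two standard codings, and recovers a coding from
three prescribed weights.
"""

import numpy as np

from epiblup import interaction_weight_table, solve_coding_from_weights

for coding in [(-1, 0, 1), (0, 1, 2)]:
    table = interaction_weight_table(coding)
    print(f"coding {coding}: implicit interaction weights (rows/cols = aa, aA, AA)")
    print(np.array2string(table.a, prefix="  "), end="\n\n")

# The symmetric coding zeroes every combination with a heterozygote; the
# dosage coding zeroes every combination with the reference homozygote aa.

print("prescribe a_11 = 1, a_12 = 2, a_23 = 6 and solve for the coding:")
sol = solve_coding_from_weights([((1, 1), 1.0), ((1, 2), 2.0), ((2, 3), 6.0)])
coding = tuple(round(v, 9) for v in sol.coding)
print(f"  coding = {coding} (determined up to a global sign: {sol.global_sign_only})")
print(f"  implied remaining weight a_33 = {sol.implied.a[2, 2]:g}")
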