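"""The cost of not knowing which allele to count, worked exactly.

Two binary loci interact: one corner of the 2x2 combination grid carries a
unit effect.  If the model codes the loci {0, 1} but each locus' orientation
(which allele is the 1) is decided by a fair coin, the best scalar fit is
perfect with probability 1/4 and useless otherwise — expected quadratic loss
0.75.  The symmetric {-1, 1} coding cannot represent the corner either, but its
loss is the same 0.75 in *every* orientation: orientation simply stops
mattering.
"""

import numpy as np

from epiblup import expected_orientation_loss

TRUE = np.array([[0.0, 0.0], [0.0, 1.0]])  # unit effect on the (A, B) corner

for coding in [(0, 1), (-1, 1)]:
    res = expected_orientation_loss(coding, TRUE, flip_prob=0.5)
    print(f"model coding {coding}:")
    for case in res.cases:
        print(
            f"  flips {case.flips}: prob {case.probability:.2f}, "
            f"best h = {case.h_opt:+.2f}, loss = {case.loss:.2f}"
        )
    print(f"  expected loss = {res.expected_loss:.2f}\n")
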