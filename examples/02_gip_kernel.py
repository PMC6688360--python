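"""Gaussian interaction-profile kernel similarity from an association matrix.

Diseases that associate with overlapping miRNA sets get a high kernel
value; the bandwidth is normalised by the mean squared profile norm so the
kernel adapts to the density of the network.
"""

import numpy as np

from mlmda import AssociationMatrix, GipParams, gip_matrix

# three diseases: d1 and d2 share most partners, d3 is disjoint
A = AssociationMatrix(
    np.array([
        [1, 1, 1, 0, 0],
        [1, 1, 0, 0, 0],
        [0, 0, 0, 1, 1],
    ]),
    ["d1", "d2", "d3"],
    ["m1", "m2", "m3", "m4", "m5"],
)

kd = gip_matrix(A, "diseases", GipParams(gamma_prime=1.0))
print("disease GIP kernel:")
print(kd.to_frame().round(4).to_string())

km = gip_matrix(A, "mirnas", GipParams(gamma_prime=1.0))
print("\nmiRNA GIP kernel (m1 vs m2, identical profiles):", km["m1", "m2"])

# KD(d1,d2) is high (profiles differ in one miRNA), KD(d1,d3) is low
# (completely disjoint profiles).  m1 and m2 have identical interaction
# profiles, so their kernel similarity is exactly 1.
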