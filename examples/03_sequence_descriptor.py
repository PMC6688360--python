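"""Fixed-length k-mer/SVD descriptors for precursor miRNA sequences.

Precursors differ in length, so a direct positional encoding cannot feed
a classifier.  The 3-mer one-hot matrix (64 x L-2) is reduced by
truncated SVD to 64 x 5 and flattened, giving every precursor the same
320-dimensional descriptor.
"""

import numpy as np

from mlmda import SequenceRecord, kmer_matrix, svd_reduce

rng = np.random.default_rng(0)
for length in (60, 75, 90):
    seq = "".join(rng.choice(list("ACGU"), size=length))
    km = kmer_matrix(SequenceRecord(f"mir-{length}", seq), k=3)
    desc = svd_reduce(km, rank=5)
    energy = np.linalg.norm(desc.reduced) ** 2 / np.linalg.norm(km.M) ** 2
    print(
        f"length {length:3d} nt: k-mer matrix {km.M.shape} -> descriptor "
        f"{desc.reduced.shape}, flattened {len(desc.f_seq)}, "
        f"top-5 singular energy {energy:.2f}"
    )

# Whatever the sequence length, the descriptor is 64 x 5 = 320 numbers;
# the energy fraction shows how much of the positional matrix the five
# retained singular components capture.
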