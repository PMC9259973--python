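"""K-GASVD: learn back a planted multivector dictionary.

2000 two-sparse columns are generated from 32 planted atoms (real scalar
gains pin the per-atom gauge, see docs/methods.md); the trainer should
re-discover nearly all atoms and its error history must never increase.
"""

import numpy as np

from gafuse import kgasvd, make_sparse_problem, match_atoms

prob = make_sparse_problem(N=16, M=32, k=2, K_cols=2000, noise_sd=0.0, seed=0, gains="scalar")
state = kgasvd(prob.Q, M=32, J=2, iters=20, seed=0)

scores = match_atoms(state.dictionary, prob.D_true)
print(f"atoms recovered at |cos| ≥ 0.99: {int((scores >= 0.99).sum())}/32")
print("error history (RMS, should be non-increasing):")
print(np.round(state.error_history, 5))
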