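"""Calibrate the score threshold so that <1 chance alignment is expected.

Fits Gumbel extreme-value statistics E(s) = K*m*n*exp(-lambda*s) to the best
duplex scores of shuffled sequence pairs, inverts for the threshold, then
counts chance hits on an independent set of the same total search-space size.
"""

import numpy as np

import duplexscan as ds
from duplexscan.scoring import random_sequence

matrix = ds.default_matrix()
n_test, length = 200, 250

threshold, fit = ds.calibrate_threshold(
    matrix, m=length, n=length * n_test, target_expected_alignments=1.0,
    null_model={"length": length}, n_null_pairs=200, seed=0,
)
print(f"lambda={fit.lam:.3f}  K={fit.K:.4f}  ->  threshold {threshold}")
print(f"expected chance alignments at threshold: {fit.expected_alignments(threshold):.3f}")

rng = np.random.default_rng(1)
observed = sum(
    len(ds.align_duplex_exact(
        ds.SequenceRecord("q", random_sequence(length, rng)),
        ds.SequenceRecord("t", random_sequence(length, rng)), matrix, threshold))
    for _ in range(n_test)
)
# With a well-calibrated threshold the count should be near 1 (Poisson mean 1).
print(f"observed chance hits over an independent equal-size search space: {observed}")
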