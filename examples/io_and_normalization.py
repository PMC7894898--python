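"""Count-matrix I/O, gene filtering and TMM normalization factors.

Writes a small matrix to MatrixMarket, reads it back, removes genes with
fewer than 20 total counts, and computes library sizes with trimmed-mean
(TMM) normalization factors.  The factors multiply library sizes into
effective sizes; their log is the model offset when testing real data.
"""

import tempfile
from pathlib import Path

import numpy as np

from scmmst import CountMatrix, filter_genes, read_counts, tmm_factors, write_counts

rng = np.random.default_rng(11)
vals = rng.poisson(6.0, size=(50, 8))
vals[:5] = rng.poisson(0.3, size=(5, 8))  # low-count genes to be filtered
vals[:, 4:] *= 3  # cells 5-8 sequenced 3x deeper
cm = CountMatrix(vals, [f"g{i}" for i in range(50)], [f"c{j}" for j in range(8)])

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "counts.mtx"
    write_counts(cm, path, format="mtx")
    back = read_counts(path)
print(f"round trip through MatrixMarket: {np.array_equal(back.values, cm.values)}")

kept = filter_genes(back, min_total=20)
print(f"gene filter (total >= 20): {cm.n_genes} -> {kept.n_genes} genes")

nf = tmm_factors(kept)
print("library sizes:", nf.lib_size.astype(int))
print("TMM factors:  ", np.round(nf.tmm_factor, 3))
# Pure depth differences are absorbed by library size, so TMM factors stay
# near 1 (geometric mean exactly 1); composition biases would move them.
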