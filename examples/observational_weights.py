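"""Observational weights for excess zeros, all four estimators side by side.

Builds one gene whose counts are NB draws thinned by dropout, computes the
per-count weights under the truncated-Poisson, zero-inflated-Poisson,
truncated-NB and ZiNB-regression models, and prints the average weight
assigned to zero counts per batch.  A weight near 0 says the model considers
that zero an excess (dropout) zero; weights are always exactly 1 at nonzero
counts.
"""

import warnings

import numpy as np

from scmmst import CellDesign, CountMatrix, compute_weights

rng = np.random.default_rng(3)
n, p = 300, 3
design = CellDesign(
    batch=[f"b{i % p}" for i in range(n)],
    group=["g1" if i % 2 == 0 else "g2" for i in range(n)],
)
mu_by_batch = np.array([4.0, 8.0, 15.0])[design.batch_index]
y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu_by_batch))
y[rng.random(n) < 0.4] = 0  # dropout
cm = CountMatrix(y[None, :], ["geneA"], [f"c{i}" for i in range(n)])
print(f"gene with {np.sum(y == 0)} zeros out of {n} counts")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for method in ("trpois", "zipois", "trnb", "zinb"):
        W = compute_weights(cm, design, method).w[0]
        means = [W[(design.batch_index == j) & (y == 0)].mean() for j in range(p)]
        print(f"{method:7s} mean zero-count weight per batch: "
              + "  ".join(f"{m:.3f}" for m in means))
# Batches with larger means downweight zeros harder: a zero is less plausible
# under the fitted count distribution, so more of it is attributed to dropout.
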