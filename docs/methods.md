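# Methods

## Model

Counts for one gene are modelled by a GLMM with a fixed intercept, an
optional per-batch group effect (the alternative), and a batch random
intercept:

    g(mu_i) = alpha + g_i B_i beta + B_i b (+ offset_i),
    beta ~ N(beta0 1_p, sigma_beta^2 I_p),  b ~ N(0, sigma_b^2 I_p).

Families: Poisson, quasi-Poisson and NB (log link) for counts; binomial and
quasi-binomial (logit link) are implemented in the family layer for binary
responses but are not exercised by the count simulator.  The NB variance is
`mu + mu^2/theta`.  Testing `beta = 0` is carried out as a variance-component
score test of `sigma_beta^2 = 0` under `beta0 = 0`; both hypotheses share
the same reduced null model, so the statistic applies to the joint null.
This is also the method's main structural limitation: power against a
homogeneous effect (`beta0 != 0`, `sigma_beta^2 = 0`) comes only indirectly
through the induced per-batch contrasts.

## Null-model fitting (PQL)

The null fit uses penalized quasi-likelihood: IRLS working responses, and,
per iteration, an exact 1-D REML profile for the batch variance.  Because
the batch is the only grouping factor, the working covariance
`Sigma = W^{-1} + lambda B B'` is block diagonal and every REML evaluation
reduces to per-batch sums; the profile is solved by golden-section search on
`log lambda` over [1e-8, 1e3] (boundary reported as 0).  The REML criterion
profiles a residual scale `phi` alongside the variance ratio
`gamma = sigma_b^2 / phi`; this makes the fitted `alpha`, `b`, `mu0`
exactly invariant to a uniform rescaling of observational weights (pure
likelihood scaling), and `sigma_b^2 = gamma * phi` is reported.  Outer
tolerance 1e-8 relative change, at most 100 iterations; non-convergence is
flagged, never raised.

NB `theta` is profiled by alternating the PQL fit with a 1-D maximization of
the (weight-multiplied) NB log-likelihood on `log theta` in [1e-3, 1e5]
(golden-section; at most 10 alternations).  Weighted fits use the
observational weights as multiplicative factors on the IRLS working weights,
i.e. as case weights; the same weights enter the theta likelihood.  All
fits are vectorized across genes: a 2,000 x 250 NB matrix fits in ~15 s on
one core.

Observational weights below 1e-8 are floored to keep the IRLS systems
well-posed.  All-zero genes are non-estimable and surface as p = 1 with a
failure flag (the "NA as 1" convention); no per-gene failure aborts a run.

## Score statistic and p-values

`T = ||G_B' (W) Phi (y - mu0)||^2 / tau` is computed without any n x n
matrix.  Its null law is `sum xi_i chisq_1` with `xi` the eigenvalues of
`E = G_B' P G_B` (weighted: `E'_w = G_B' W P W G_B` — the projection P keeps
its unweighted structural form, with `V`, `sigma_b^2`, `mu0` taken from the
weighted null fit; the residuals are treated as estimated by the unweighted
GLMM.  This approximation degrades as the zero fraction grows).  `P` is
assembled from the per-batch rank-one Woodbury inverse of
`Sigma = V + sigma_b^2 B B'`.

Eigenvalues below `max(xi) * 1e-8` are dropped and numerically negative ones
set to 0.  Tail probabilities use Imhof's characteristic-function inversion
integrated on a uniform Simpson grid (>= 24 points per oscillation,
truncation point chosen from an analytic envelope bound targeting 1e-8,
point budget 5e5, Richardson extrapolation of the discretization error).  A
single eigenvalue short-circuits to the exact chi-square tail.  If the
estimated error exceeds 1e-4 the Liu–Tang–Zhang moment-matching
approximation is used instead; the backend is recorded per gene.  For quasi
families, `tau` is the residual deviance of the null fit divided by `n - 1`
(random effects are not counted against the degrees of freedom) and divides
T directly, as in the displayed statistic.

## Observational weights

All four estimators act under the null (group labels are never consulted)
and leave nonzero counts at weight 1:

* **trpois** — per batch, the truncated-Poisson rate solves
  `lambda/(1 - e^-lambda) = mean(nonzero counts)` (Brent, residual < 1e-8);
  zero weight `n1 e^-lambda / (n0 (1 - e^-lambda))`, clipped into (0, 1].
  The unclipped value satisfies `w n0/(w n0 + n1) = f(0; lambda)` exactly.
* **zipois** — per batch, EM on the zero-inflated Poisson; weights are
  posterior probabilities of the Poisson component.  The EM depends on the
  data only through (n, n0, sum y), so all gene x batch fits run as a single
  vectorized recursion.
* **trnb** — per batch, the truncated-NB moment equations reduce to a 1-D
  root-find in theta (truncated-ML fallback when no admissible root exists;
  theta clamped to [0.01, 1e4]).  A low-confidence flag marks theta < 2
  (unstable moment estimator) and theta >= 1e3 (near-Poisson data cannot
  resolve the dispersion).  The common dispersion is the harmonic mean over
  batches whose fit succeeded — failed batches are excluded — and each
  batch's mean is re-solved from the truncated-mean equation at the common
  theta before evaluating the zero weight.
* **zinb** — one EM regression per gene on all cells with batch fixed
  effects in the mean (log link) and zero (logit) models and a gene-level
  theta.  With a batch-saturated design both M-steps are closed-form
  (responsibility-weighted batch means; mean responsibility per batch), and
  theta is profiled 1-D.  This gene-wise regression stands in for a
  latent-factor ZiNB model: it is the one deliberate methodological
  substitution in the package, chosen for self-containment, and matches the
  intent of fitting batch fixed effects without group effects.

Failures of any weight fit (all-zero batches, degenerate samples) degrade to
weight 1 with a warning — no cell is dropped and no run aborts.

## Simulator

Per gene: `b ~ N(0, sigma_b2 I_p)`; DE genes (deterministically the first
`floor(de_prop G)` genes) draw `beta ~ N(beta0 1_p, sigma_beta2 I_p)`;
`eta_i = mu0 + g_i beta_batch(i) + b_batch(i)`; counts are Poisson or NB;
dropout zeroes counts where `z_i ~ Bern(logit^{-1}(mu_pi + b_batch(i)))` is
0.  Defaults state the reference design: 250 cells dealt round-robin into
5 batches x 2 groups (so every batch contains both groups and the test is
identifiable), `mu0 = 5`, `sigma_b2 = 0.25`, `de_prop = 0.1`.  The same `b`
enters counts and dropout (`dropout_batch="shared"`); an independent redraw
is available since the shared choice is a modelling decision, not a
constraint.  One `numpy` Generator per dataset with a fixed draw order makes
outputs bit-reproducible from the seed.

What the generator does **not** emulate: library-size variation (it is
depth-homogeneous, so simulation-based analyses run without normalization
offsets), outlier expression, gene–gene correlation, and mean–dispersion
trends.  A green calibration test therefore establishes correct behaviour
under the stated GLMM world, not under every real dataset.

## Normalization

TMM factors are computed against the cell whose 75th count quantile
(library-size scaled) is closest to the mean such quantile; log-ratios are
doubly trimmed (30% on M, 5% on A, the published defaults), precision
weighted, and factors rescaled to geometric mean 1.  Factors are estimated
from raw counts and enter the GLMM as the per-cell offset
`log(lib_size * factor / 1e6)`; the counts themselves are modelled raw.
Whether CPM should instead be applied to the modelled counts is ambiguous in
the source material; the offset mechanism is the standard GLM resolution and
is what this package does.  The default gene filter removes genes with
fewer than 20 total counts.

## Evaluation conventions

PCER is the fraction of null genes with *unadjusted* p <= alpha; FDP–TPR
curves and ROC AUCs use BH-adjusted p-values scored as `1 - p_adj`
(tie-aware, equivalent to the Mann–Whitney form).  `FDP = FP/max(1, FP+TP)`
so zero declarations give 0.  These conventions are fixed, not configurable.

## Known limitations

* PQL point estimates of `sigma_b^2` carry the usual small-sample bias with
  few batches (p = 5); the acceptance-scale recovery check sees ~10-15%
  downward bias at 1,000 cells.
* The `E'_w` approximation worsens with the zero fraction; in practice this
  shows up as growing conservatism of the weighted tests.
* The statistic targets batch-heterogeneous group effects; it does not
  jointly test the homogeneous effect.
* Quasi-family `tau` placement follows the displayed statistic (divides T);
  rescaling `Sigma` instead would be an alternative not implemented.
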