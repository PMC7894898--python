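"""Observational weights for excess zeros.

Four estimators, all independent of the GLMM and all computed under the null
of no group effect:

* ``trpois`` — zero-truncated Poisson per batch: lambda solves
  ``lambda / (1 - exp(-lambda)) = mean of nonzero counts``; the zero weight is
  ``n1 exp(-lambda) / (n0 (1 - exp(-lambda)))``.
* ``zipois`` — zero-inflated Poisson per batch fitted by EM; the zero weight
  is the posterior probability that a zero arose from the Poisson component.
* ``trnb`` — zero-truncated negative binomial per batch by moment equations
  (ML fallback), with the dispersion pooled across batches by harmonic mean;
  the zero weight is ``n1 p0 / (n0 (1 - p0))`` with ``p0 = (theta/(theta+mu))^theta``.
* ``zinb`` — gene-wise zero-inflated NB regression with batch fixed effects in
  both the mean and the zero-inflation model, fitted by EM on all cells.

Every method leaves nonzero counts at weight 1 and downweights zeros into
(0, 1]; failed fits degrade to weight 1 with a warning, never abort a run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.special import gammaln

from .io_norm import CellDesign, CountMatrix

WEIGHT_METHODS = ("none", "trpois", "zipois", "trnb", "zinb")
_W_EPS = 1e-12


@dataclass
class ZeroInflationFit:
    """Fitted zero-inflated distribution for one batch of counts."""

    pi_hat: float
    theta_params: dict
    n0: int
    n1: int
    converged: bool
    loglik_path: np.ndarray | None = None


@dataclass
class WeightMatrix:
    """Genes x cells observational weights in (0, 1]; 1 at nonzero counts."""

    w: np.ndarray
    method: str

    def to_tsv(self, path: str | Path, gene_ids, cell_ids) -> None:
        df = pd.DataFrame(self.w, index=gene_ids, columns=cell_ids)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


# ----------------------------------------------------------------------------
# truncated Poisson
# ----------------------------------------------------------------------------


def trpois_lambda(ybar_nonzero: float) -> float:
    """Solve ``lam / (1 - exp(-lam)) = ybar`` for the truncated-Poisson rate.

    The truncated mean is >= 1 by construction; ``ybar == 1`` corresponds to
    the degenerate limit lam -> 0.
    """
    ybar = float(ybar_nonzero)
    if ybar < 1.0:
        raise ValueError("truncated Poisson mean cannot be below 1")
    if ybar <= 1.0 + 1e-12:
        return 1e-10

    def f(lam):
        return lam / (-np.expm1(-lam)) - ybar

    hi = max(2.0 * ybar, 1.0)
    while f(hi) < 0:
        hi *= 2.0
    return brentq(f, 1e-12, hi, xtol=1e-12, rtol=8.9e-16)


def trpois_weights(y_batch: np.ndarray) -> np.ndarray:
    """Per-count weights for one batch under the zero-truncated Poisson."""
    y = np.asarray(y_batch)
    nz = y > 0
    n1 = int(nz.sum())
    n0 = y.size - n1
    w = np.ones(y.size)
    if n1 == 0:
        warnings.warn("batch with all counts zero: weights left at 1", stacklevel=2)
        return w
    if n0 == 0:
        return w
    lam = trpois_lambda(y[nz].mean())
    f0 = np.exp(-lam)
    w0 = n1 * f0 / (n0 * (1.0 - f0))
    w[~nz] = min(max(w0, _W_EPS), 1.0)
    return w


# ----------------------------------------------------------------------------
# zero-inflated Poisson (EM)
# ----------------------------------------------------------------------------


def _zip_loglik(n0, y_sum, y_nz, pi, lam):
    ll0 = n0 * np.log(pi + (1 - pi) * np.exp(-lam)) if n0 else 0.0
    ll1 = y_nz.size * np.log1p(-pi) + y_sum * np.log(lam) - y_nz.size * lam
    ll1 -= gammaln(y_nz + 1).sum()
    return ll0 + ll1


def zipois_fit(y_batch: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> ZeroInflationFit:
    """EM fit of the zero-inflated Poisson to one batch of counts.

    The E-step assigns each zero its responsibility for the point mass; the
    M-step updates pi (mean responsibility) and lambda (mean of counts among
    observations attributed to the Poisson component).  The observed-data
    log-likelihood is non-decreasing across iterations.
    """
    y = np.asarray(y_batch, dtype=float)
    nz = y > 0
    n1 = int(nz.sum())
    n0 = y.size - n1
    if n1 == 0:
        raise ValueError("cannot fit ZIP to an all-zero sample")
    y_nz = y[nz]
    y_sum = y_nz.sum()
    n = y.size
    if n0 == 0:
        return ZeroInflationFit(0.0, {"lam": y.mean()}, 0, n1, True,
                                loglik_path=np.array([_zip_loglik(0, y_sum, y_nz, 0.0, y.mean())]))
    pi, lam = 0.5 * n0 / n, max(y_nz.mean(), 1e-6)
    path = [_zip_loglik(n0, y_sum, y_nz, pi, lam)]
    converged = False
    for _ in range(max_iter):
        gamma = pi / (pi + (1 - pi) * np.exp(-lam))  # zero -> point mass
        pi_new = n0 * gamma / n
        lam_new = y_sum / (n - n0 * gamma)
        path.append(_zip_loglik(n0, y_sum, y_nz, pi_new, lam_new))
        if abs(pi_new - pi) < tol and abs(lam_new - lam) < tol * (1 + lam):
            pi, lam = pi_new, lam_new
            converged = True
            break
        pi, lam = pi_new, lam_new
    return ZeroInflationFit(float(pi), {"lam": float(lam)}, n0, n1, converged,
                            loglik_path=np.array(path))


def zero_inflated_weight(y, fit: ZeroInflationFit, family: str = "poisson"):
    """Posterior probability that count ``y`` comes from the count component.

    ``w = (1 - pi) f(y) / f_ZI(y)``; equals 1 for any nonzero y.
    """
    y = np.asarray(y)
    pi = fit.pi_hat
    if family == "poisson":
        f0 = np.exp(-fit.theta_params["lam"])
    elif family == "nb":
        mu, theta = fit.theta_params["mu"], fit.theta_params["theta"]
        f0 = (theta / (theta + mu)) ** theta
    else:
        raise ValueError(f"unknown family {family!r}")
    w0 = (1 - pi) * f0 / (pi + (1 - pi) * f0) if pi > 0 else 1.0
    w = np.where(y > 0, 1.0, np.clip(w0, _W_EPS, 1.0))
    return w if w.ndim else float(w)


# ----------------------------------------------------------------------------
# truncated negative binomial
# ----------------------------------------------------------------------------


def _trnb_p0(mu, theta):
    return (theta / (theta + mu)) ** theta


def _trnb_loglik(y_nz, mu, theta):
    p0 = _trnb_p0(mu, theta)
    ll = (
        gammaln(y_nz + theta)
        - gammaln(theta)
        - gammaln(y_nz + 1)
        + theta * np.log(theta / (theta + mu))
        + y_nz * np.log(mu / (theta + mu))
    )
    return np.sum(ll) - y_nz.size * np.log1p(-p0)

_THETA_CLAMP = (0.01, 1e4)


def trnb_fit(y_batch: np.ndarray) -> tuple[float, float, bool]:
    """Estimate (mu, theta) of a zero-truncated NB from one batch.

    Solves the first two truncated-moment equations: with ``m1, m2`` the
    truncated sample moments and ``p0 = (theta/(theta+mu))^theta``,

        m1 = mu / (1 - p0),   m2/m1 = 1 + mu (1 + 1/theta),

    reducing to a 1-D root-find in theta.  Falls back to truncated-NB maximum
    likelihood when the moment system has no admissible root.  Returns
    ``(mu_hat, theta_hat, low_confidence)``; the flag is set when
    theta_hat < 2, where the moment estimator is known to be unstable.
    """
    y = np.asarray(y_batch, dtype=float)
    y_nz = y[y > 0]
    if y_nz.size < 2 or np.all(y_nz == y_nz[0]):
        raise ValueError("degenerate sample: need >= 2 distinct nonzero values")
    m1 = y_nz.mean()
    m2 = np.mean(y_nz**2)
    c = m2 / m1 - 1.0  # = mu (1 + 1/theta)
    lo, hi = _THETA_CLAMP

    def resid(theta):
        mu = c * theta / (theta + 1.0)
        return mu / (1.0 - _trnb_p0(mu, theta)) - m1

    mu_hat = theta_hat = None
    if c > 0:
        try:
            r_lo, r_hi = resid(lo), resid(hi)
            if np.isfinite(r_lo) and np.isfinite(r_hi) and r_lo * r_hi < 0:
                theta_hat = brentq(resid, lo, hi, xtol=1e-10)
                mu_hat = c * theta_hat / (theta_hat + 1.0)
        except ValueError:
            pass
    if theta_hat is None:
        # ML fallback on (log mu, log theta)
        def nll(x):
            mu, theta = np.exp(x)
            return -_trnb_loglik(y_nz, mu, theta)

        x0 = np.log([max(m1, 0.1), 1.0])
        opt = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        mu_hat, theta_hat = np.exp(opt.x)
    theta_hat = float(np.clip(theta_hat, lo, hi))
    # flagged: small theta (known-unstable moment estimator) or a near-Poisson
    # fit where the truncated moments cannot resolve the dispersion
    low_confidence = theta_hat < 2.0 or theta_hat >= 1e3
    return float(mu_hat), theta_hat, low_confidence


def harmonic_mean(values) -> float:
    """Harmonic mean, used to pool per-batch NB dispersions."""
    v = np.asarray(values, dtype=float)
    if v.size == 0 or np.any(v <= 0):
        raise ValueError("harmonic mean needs positive values")
    return float(v.size / np.sum(1.0 / v))


def _trnb_mu_at_theta(m1: float, theta: float) -> float:
    """Truncated-mean equation ``mu / (1 - p0(mu, theta)) = m1`` solved for mu."""

    def f(log_mu):
        mu = np.exp(log_mu)
        return mu / (1.0 - _trnb_p0(mu, theta)) - m1

    lo, hi = np.log(1e-8), np.log(max(10.0 * m1, 1.0))
    if f(lo) > 0:  # truncated mean above m1 even at tiny mu: mu -> 0 limit
        return 1e-8
    return float(np.exp(brentq(f, lo, hi, xtol=1e-12)))


def trnb_weights(cm_gene: np.ndarray, design: CellDesign) -> np.ndarray:
    """Truncated-NB weights for one gene with a batch-common dispersion.

    theta is estimated per batch, pooled by harmonic mean over batches whose
    fit succeeded, then the per-batch mean is re-solved from the truncated
    mean equation at the common theta before evaluating the zero weight.
    """
    y = np.asarray(cm_gene)
    w = np.ones(y.size)
    thetas, batch_idx_ok = [], []
    for j in range(design.n_batches):
        sel = design.batch_index == j
        try:
            _, th, _ = trnb_fit(y[sel])
            thetas.append(th)
            batch_idx_ok.append(j)
        except ValueError:
            warnings.warn(f"truncated-NB fit failed for batch {design.batch_levels[j]}; "
                          "weights left at 1", stacklevel=2)
    if not thetas:
        return w
    theta_common = harmonic_mean(thetas)
    for j in batch_idx_ok:
        sel = design.batch_index == j
        yb = y[sel]
        nz = yb > 0
        n1, n0 = int(nz.sum()), int((~nz).sum())
        if n0 == 0 or n1 == 0:
            continue
        mu = _trnb_mu_at_theta(yb[nz].mean(), theta_common)
        p0 = _trnb_p0(mu, theta_common)
        w0 = n1 * p0 / (n0 * (1.0 - p0))
        wb = w[sel]
        wb[~nz] = min(max(w0, _W_EPS), 1.0)
        w[sel] = wb
    return w


# ----------------------------------------------------------------------------
# gene-wise ZiNB regression with batch fixed effects
# ----------------------------------------------------------------------------


def _zinb_obs_loglik(y, mu, pi, theta):
    p0 = (theta / (theta + mu)) ** theta
    nb = np.exp(
        gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
        + theta * np.log(theta / (theta + mu)) + y * np.log(np.where(y > 0, mu, 1.0) / (theta + mu))
    )
    nb = np.where(y > 0, nb, p0)
    dens = np.where(y > 0, (1 - pi) * nb, pi + (1 - pi) * nb)
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


def zinb_regression_weights(
    y_gene: np.ndarray,
    design: CellDesign,
    max_iter: int = 100,
    tol: float = 1e-8,
    return_loglik_path: bool = False,
):
    """EM fit of a gene-wise ZiNB regression; returns posterior NB weights.

    Mean model: log mu = batch fixed effects (batch-saturated, so the weighted
    M-step mean is the responsibility-weighted batch mean).  Zero model:
    logit pi = batch fixed effects (per-batch mean responsibility).  A single
    gene-level theta is profiled by 1-D likelihood maximization each M-step.
    """
    y = np.asarray(y_gene, dtype=float)
    if not (y > 0).any():
        raise ValueError("all-zero gene: ZiNB regression not estimable")
    bi = design.batch_index
    p = design.n_batches
    nz = y > 0
    path: list[float] = []
    if not (~nz).any():
        w = np.ones(y.size)
        return (w, np.array(path)) if return_loglik_path else w

    # init: batch means from nonzero counts, pi from zero fraction
    mu_b = np.array([max(y[(bi == j) & nz].mean(), 1e-3) if ((bi == j) & nz).any() else 1e-3
                     for j in range(p)])
    pi_b = np.array([np.mean(y[bi == j] == 0) * 0.5 for j in range(p)])
    m, v = y[nz].mean(), y[nz].var()
    theta = float(np.clip(m**2 / max(v - m, m * 1e-2), 1e-3, 1e4))

    ll_prev = -np.inf
    converged = False
    from .glmm import _GOLDEN  # same golden-section constant

    for _ in range(max_iter):
        mu = mu_b[bi]
        pi = np.clip(pi_b[bi], 1e-10, 1 - 1e-10)
        p0 = (theta / (theta + mu)) ** theta
        gamma = np.where(nz, 0.0, pi / (pi + (1 - pi) * p0))  # zero -> point mass
        resp = 1.0 - gamma
        # M-step: batch-saturated closed forms
        for j in range(p):
            sel = bi == j
            denom = resp[sel].sum()
            mu_b[j] = max((resp[sel] * y[sel]).sum() / max(denom, 1e-10), 1e-6)
            pi_b[j] = gamma[sel].mean()
        mu = mu_b[bi]

        def nll_theta(logth):
            th = np.exp(logth)
            ll = (gammaln(y + th) - gammaln(th) + th * np.log(th)
                  - (y + th) * np.log(th + mu) + y * np.log(np.where(y > 0, mu, 1.0)))
            return -(resp * ll).sum()

        lo, hi = np.log(1e-3), np.log(1e4)
        for _k in range(40):
            x1 = hi - _GOLDEN * (hi - lo)
            x2 = lo + _GOLDEN * (hi - lo)
            if nll_theta(x1) > nll_theta(x2):
                lo = x1
            else:
                hi = x2
        theta = float(np.exp(0.5 * (lo + hi)))
        ll = _zinb_obs_loglik(y, mu_b[bi], np.clip(pi_b[bi], 1e-10, 1 - 1e-10), theta)
        path.append(ll)
        if abs(ll - ll_prev) < tol * (1 + abs(ll)):
            converged = True
            break
        ll_prev = ll
    if not converged:
        warnings.warn("ZiNB EM did not converge; using last iterate", stacklevel=2)
    mu = mu_b[bi]
    pi = np.clip(pi_b[bi], 1e-10, 1 - 1e-10)
    p0 = (theta / (theta + mu)) ** theta
    w = np.where(nz, 1.0, np.clip((1 - pi) * p0 / (pi + (1 - pi) * p0), _W_EPS, 1.0))
    return (w, np.array(path)) if return_loglik_path else w


# ----------------------------------------------------------------------------
# dispatch
# ----------------------------------------------------------------------------


def _per_batch_weights(y: np.ndarray, design: CellDesign, fn) -> np.ndarray:
    w = np.ones(y.size)
    for j in range(design.n_batches):
        sel = design.batch_index == j
        try:
            w[sel] = fn(y[sel])
        except ValueError as exc:
            warnings.warn(f"weight fit failed for batch {design.batch_levels[j]} "
                          f"({exc}); weights left at 1", stacklevel=3)
    return w


def _zipois_batch_weights(y_batch: np.ndarray) -> np.ndarray:
    fit = zipois_fit(y_batch)
    return np.asarray(zero_inflated_weight(y_batch, fit, "poisson"))


def compute_weights(cm: CountMatrix, design: CellDesign, method: str = "zipois") -> WeightMatrix:
    """Genes x cells observational weights under the chosen model.

    ``trpois``/``zipois``/``trnb`` fit per batch; ``zinb`` fits one regression
    per gene on all cells.  Per-gene failures degrade to all-ones rows with a
    warning so a run never aborts.
    """
    if method not in WEIGHT_METHODS:
        raise ValueError(f"unknown weight method {method!r}; choose from {WEIGHT_METHODS}")
    G, n = cm.values.shape
    if method == "none":
        return WeightMatrix(np.ones((G, n)), "none")
    if method == "zipois":
        return WeightMatrix(_zipois_matrix(cm.values, design), "zipois")
    W = np.ones((G, n), dtype=float)
    for g in range(G):
        y = cm.values[g]
        if not (y > 0).any():
            warnings.warn(f"gene {cm.gene_ids[g]} is all-zero; weights left at 1", stacklevel=2)
            continue
        try:
            if method == "trpois":
                W[g] = _per_batch_weights(y, design, trpois_weights)
            elif method == "trnb":
                W[g] = trnb_weights(y, design)
            elif method == "zinb":
                W[g] = zinb_regression_weights(y, design)
        except ValueError as exc:
            warnings.warn(f"weights failed for gene {cm.gene_ids[g]}: {exc}", stacklevel=2)
    return WeightMatrix(W, method)


def _zipois_matrix(Y: np.ndarray, design: CellDesign, max_iter: int = 200, tol: float = 1e-10):
    """Vectorized per-(gene, batch) ZIP EM on sufficient statistics.

    The EM updates depend on the data only through (n, n0, sum y), so all
    gene x batch fits run as array recursions.
    """
    G, n = Y.shape
    Bm = design.batch_onehot
    nz = (Y > 0).astype(float)
    n_gb = Bm.sum(axis=0)[None, :]  # 1 x p
    n1 = nz @ Bm
    n0 = n_gb - n1
    ysum = Y @ Bm
    ok = n1 > 0  # all-zero cells in a batch -> weights stay 1
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(ok, 0.5 * n0 / n_gb, 0.0)
        lam = np.where(ok, ysum / np.maximum(n1, 1.0), 1.0)
    for _ in range(max_iter):
        gamma = pi / (pi + (1 - pi) * np.exp(-lam))
        gamma = np.where(n0 > 0, gamma, 0.0)
        pi_new = np.where(ok, n0 * gamma / n_gb, 0.0)
        lam_new = np.where(ok, ysum / np.maximum(n_gb - n0 * gamma, 1e-10), 1.0)
        if np.all(np.abs(pi_new - pi) < tol) and np.all(np.abs(lam_new - lam) < tol * (1 + lam)):
            pi, lam = pi_new, lam_new
            break
        pi, lam = pi_new, lam_new
    f0 = np.exp(-lam)
    w0 = np.where(pi > 0, (1 - pi) * f0 / (pi + (1 - pi) * f0), 1.0)
    w0 = np.clip(w0, _W_EPS, 1.0)
    W = np.where(Y > 0, 1.0, w0[:, design.batch_index])
    return W
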