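"""Null-model GLMM fitting by penalized quasi-likelihood (PQL).

The reduced (null) model for one gene is

    g(mu_0i) = alpha + B_i b (+ offset_i),      b ~ N(0, sigma_b^2 I_p),

i.e. an intercept plus a random intercept per batch.  Fitting alternates IRLS
on the working response with a 1-D REML profile over sigma_b^2; because the
only grouping factor is the batch, the working-model covariance is block
diagonal per batch and every REML evaluation reduces to closed-form per-batch
aggregates.  All fits are vectorized over genes: a whole genes x cells matrix
is fitted in a handful of dense numpy passes, which is what makes testing
thousands of genes tractable.

Observational weights, when supplied, multiply the IRLS working weights
(weighted GLMM).  For the negative binomial family the dispersion theta is
profiled by alternating the PQL fit with a 1-D maximization of the (weighted)
NB log-likelihood in theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

from .io_norm import CellDesign

_SIGMA_B2_LO = 1e-8
_SIGMA_B2_HI = 1e3
_THETA_LO = 1e-3
_THETA_HI = 1e5
_WEIGHT_FLOOR = 1e-8
_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0

_COUNT_FAMILIES = ("poisson", "quasipoisson", "nb")
_BINOM_FAMILIES = ("binomial", "quasibinomial")


class NonEstimableError(ValueError):
    """Raised when a gene carries no information (e.g. all counts zero)."""


@dataclass
class FamilySpec:
    """Distributional family of the GLMM.

    Count families use the log link, binomial families the logit link.
    ``theta`` is the NB dispersion (variance mu + mu^2/theta); ``tau`` is the
    quasi-likelihood dispersion, fixed at 1 for binomial/Poisson/NB and
    estimated from the residual deviance for the quasi families.
    """

    family: str
    theta: float | None = None
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in _COUNT_FAMILIES + _BINOM_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "nb" and self.theta is not None and self.theta <= 0:
            raise ValueError("NB dispersion theta must be positive")

    @property
    def link(self) -> str:
        return "log" if self.family in _COUNT_FAMILIES else "logit"

    @property
    def is_quasi(self) -> bool:
        return self.family in ("quasipoisson", "quasibinomial")


@dataclass
class NullModelFit:
    """Fitted reduced null GLMM for one gene."""

    alpha_hat: float
    b_hat: np.ndarray
    sigma_b2_hat: float
    mu0_hat: np.ndarray
    theta_hat: float | None
    tau_hat: float
    v_diag: np.ndarray
    phi_diag: np.ndarray
    converged: bool
    n_iter: int
    family: FamilySpec = field(repr=False, default=None)


def variance_diag(mu0: np.ndarray, family: FamilySpec) -> tuple[np.ndarray, np.ndarray]:
    """Diagonals of V-hat = (g'(mu))^2 Var(y) and of Phi-hat.

    Poisson / quasi-Poisson: v = 1/mu, phi = 1.
    NB: v = 1/mu + 1/theta, phi = 1/(1 + mu/theta).
    Binomial / quasi-binomial: v = 1/[mu (1-mu)], phi = 1.
    """
    mu0 = np.asarray(mu0, dtype=float)
    if np.any(mu0 <= 0):
        raise ValueError("mu0 must be positive")
    if family.link == "logit" and np.any(mu0 >= 1):
        raise ValueError("binomial mean must lie in (0,1)")
    if family.family == "nb":
        if family.theta is None:
            raise ValueError("NB family requires theta")
        v = 1.0 / mu0 + 1.0 / family.theta
        phi = 1.0 / (1.0 + mu0 / family.theta)
    elif family.link == "logit":
        v = 1.0 / (mu0 * (1.0 - mu0))
        phi = np.ones_like(mu0)
    else:
        v = 1.0 / mu0
        phi = np.ones_like(mu0)
    return v, phi


def estimate_quasi_dispersion(fit: NullModelFit, y: np.ndarray, family: FamilySpec) -> float:
    """tau-hat = residual deviance / (n - 1); 1 for non-quasi families."""
    y = np.asarray(y, dtype=float)
    if y.size <= 1:
        raise ValueError("need n > 1 to estimate dispersion")
    if not family.is_quasi:
        return 1.0
    mu = fit.mu0_hat
    if family.family == "quasipoisson":
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        dev = 2.0 * np.sum(term - (y - mu))
    else:  # quasibinomial, binary responses
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
            t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
        dev = 2.0 * np.sum(t1 + t2)
    tau = float(dev) / (y.size - 1)
    return max(tau, 1e-10)


# ----------------------------------------------------------------------------
# vectorized PQL machinery
# ----------------------------------------------------------------------------


def _working_quantities(Y, eta, off, w, family, theta):
    """Working weights W and centered working response z - offset (both G x n)."""
    if family in _COUNT_FAMILIES:
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        z = eta - off + (Y - mu) / mu
        if family == "nb":
            W = w / (1.0 / mu + 1.0 / theta)
        else:
            W = w * mu
    else:
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        z = eta - off + (Y - mu) / (mu * (1.0 - mu))
        W = w * mu * (1.0 - mu)
    return np.maximum(W, 1e-300), z, mu


def _reml_quad(loggam, S, T, Q, Stot, Ttot, Qtot):
    """GLS pieces at variance ratio gamma: (quad form, logdet terms, A, alpha)."""
    gam = np.exp(loggam)
    c = 1.0 / (1.0 + gam[:, None] * S)
    A = np.sum(S * c, axis=1)
    alpha = np.sum(T * c, axis=1) / A
    quad = Qtot - 2.0 * alpha * Ttot + alpha**2 * Stot
    quad = quad - gam * np.sum((T - alpha[:, None] * S) ** 2 * c, axis=1)
    logdet = np.sum(np.log1p(gam[:, None] * S), axis=1)
    return np.maximum(quad, 1e-300), logdet, A, alpha


def _reml_objective(loggam, S, T, Q, Stot, Ttot, Qtot, n):
    """REML deviance in gamma = sigma_b^2 / phi with the residual scale phi
    profiled out in closed form (phi_hat = quad / (n - 1))."""
    quad, logdet, A, _ = _reml_quad(loggam, S, T, Q, Stot, Ttot, Qtot)
    return logdet + np.log(A) + (n - 1) * np.log(quad)


def _profile_sigma_b2(S, T, Q, n, fix_loglam=None, n_iter=64):
    """Golden-section REML profile over log gamma, vectorized over genes.

    Returns (gamma, phi, alpha, b): profiling the residual scale phi makes the
    fitted alpha/b invariant to a uniform rescaling of the observational
    weights (pure likelihood scaling); sigma_b^2 = gamma * phi.
    """
    G = S.shape[0]
    Stot, Ttot, Qtot = S.sum(axis=1), T.sum(axis=1), Q.sum(axis=1)
    if fix_loglam is not None:
        best = np.full(G, fix_loglam)
    else:
        lo = np.full(G, np.log(_SIGMA_B2_LO))
        hi = np.full(G, np.log(_SIGMA_B2_HI))
        for _ in range(n_iter):
            x1 = hi - _GOLDEN * (hi - lo)
            x2 = lo + _GOLDEN * (hi - lo)
            f1 = _reml_objective(x1, S, T, Q, Stot, Ttot, Qtot, n)
            f2 = _reml_objective(x2, S, T, Q, Stot, Ttot, Qtot, n)
            move_right = f1 > f2
            lo = np.where(move_right, x1, lo)
            hi = np.where(move_right, hi, x2)
        best = 0.5 * (lo + hi)
    gam = np.exp(best)
    quad, _, A, alpha = _reml_quad(best, S, T, Q, Stot, Ttot, Qtot)
    phi = quad / (n - 1)
    c = 1.0 / (1.0 + gam[:, None] * S)
    b = gam[:, None] * (T - alpha[:, None] * S) * c
    return gam, phi, alpha, b


def _nb_loglik_theta(logtheta, Y, mu, w):
    theta = np.exp(logtheta)[:, None]
    ll = (
        gammaln(Y + theta)
        - gammaln(theta)
        + theta * np.log(theta)
        - (Y + theta) * np.log(theta + mu)
        + Y * np.log(mu)
    )
    return np.sum(w * ll, axis=1)


def _profile_theta(Y, mu, w, n_iter=32):
    """Golden-section ML profile of NB theta per gene (weighted likelihood)."""
    G = Y.shape[0]
    lo = np.full(G, np.log(_THETA_LO))
    hi = np.full(G, np.log(_THETA_HI))
    for _ in range(n_iter):
        x1 = hi - _GOLDEN * (hi - lo)
        x2 = lo + _GOLDEN * (hi - lo)
        f1 = -_nb_loglik_theta(x1, Y, mu, w)
        f2 = -_nb_loglik_theta(x2, Y, mu, w)
        move_right = f1 > f2
        lo = np.where(move_right, x1, lo)
        hi = np.where(move_right, hi, x2)
    return np.exp(0.5 * (lo + hi))


def _pql_fit_matrix(
    Y,
    design: CellDesign,
    family: str,
    theta=None,
    weights=None,
    offset=None,
    fix_sigma_b2=None,
    tol: float = 1e-8,
    max_iter: int = 100,
):
    """Vectorized PQL fit of the intercept + batch-random-intercept null model.

    Parameters are per gene: ``Y`` is G x n, ``theta`` a length-G vector for
    the NB family.  Returns dict of arrays (alpha, b, sigma_b2, eta, mu,
    converged, n_iter).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    G, n = Y.shape
    Bm = design.batch_onehot  # n x p
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    w = np.ones_like(Y) if weights is None else np.maximum(
        np.atleast_2d(np.asarray(weights, dtype=float)), _WEIGHT_FLOOR
    )
    if family in _COUNT_FAMILIES:
        eta = np.log(Y + 0.5)
    else:
        eta = np.log((Y + 0.5) / (1.5 - Y))
    theta_col = None if theta is None else np.asarray(theta, dtype=float)[:, None]
    if fix_sigma_b2 is None:
        fix_loglam = None
    elif fix_sigma_b2 <= _SIGMA_B2_LO:
        fix_loglam = -np.inf  # exact zero: plain GLM with no batch deviations
    else:
        fix_loglam = np.log(fix_sigma_b2)

    alpha = np.zeros(G)
    b = np.zeros((G, design.n_batches))
    gam = np.zeros(G)
    phi = np.ones(G)
    converged = np.zeros(G, dtype=bool)
    n_iter = np.zeros(G, dtype=int)
    for it in range(max_iter):
        W, z, _mu = _working_quantities(Y, eta, off, w, family, theta_col)
        Wz = W * z
        S = W @ Bm
        T = Wz @ Bm
        Q = (Wz * z) @ Bm
        gam_new, phi_new, alpha_new, b_new = _profile_sigma_b2(
            S, T, Q, n, fix_loglam=fix_loglam
        )
        delta = np.maximum(
            np.abs(alpha_new - alpha) / (1.0 + np.abs(alpha_new)),
            np.max(np.abs(b_new - b), axis=1) / (1.0 + np.max(np.abs(b_new), axis=1)),
        )
        alpha, b, gam, phi = alpha_new, b_new, gam_new, phi_new
        eta = alpha[:, None] + b[:, design.batch_index] + off[None, :]
        newly = (~converged) & (delta < tol)
        n_iter[newly] = it + 1
        converged |= newly
        if converged.all():
            break
    n_iter[~converged] = max_iter
    mu = (
        np.exp(np.clip(eta, -30.0, 30.0))
        if family in _COUNT_FAMILIES
        else np.clip(expit(eta), 1e-10, 1 - 1e-10)
    )
    sigma_b2 = np.where(gam <= _SIGMA_B2_LO * 1.01, 0.0, gam * phi)
    return {
        "alpha": alpha,
        "b": b,
        "sigma_b2": sigma_b2,
        "eta": eta,
        "mu": mu,
        "converged": converged,
        "n_iter": n_iter,
    }


def _moment_theta(Y):
    m = Y.mean(axis=1)
    v = Y.var(axis=1)
    excess = np.maximum(v - m, m * 1e-3)
    return np.clip(m**2 / np.maximum(excess, 1e-12), _THETA_LO, _THETA_HI)


def fit_null_glmm_matrix(
    Y,
    design: CellDesign,
    family: FamilySpec,
    weights=None,
    offset=None,
    fix_sigma_b2=None,
    max_alternations: int = 10,
):
    """Fit the null GLMM to every row of ``Y`` (genes x cells) at once.

    For the NB family with unspecified theta, alternates the PQL fit with a
    per-gene profile-likelihood update of theta (at most ``max_alternations``
    rounds).  Returns a dict of per-gene arrays; rows that carry no signal
    (all-zero) are flagged in ``failed``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    G, n = Y.shape
    failed = ~(Y > 0).any(axis=1)
    w = None if weights is None else np.atleast_2d(np.asarray(weights, dtype=float))

    if family.family == "nb" and family.theta is None:
        theta = _moment_theta(Y)
        res = None
        for _ in range(max_alternations):
            res = _pql_fit_matrix(
                Y, design, "nb", theta=theta, weights=w, offset=offset, fix_sigma_b2=fix_sigma_b2
            )
            w_eff = np.ones_like(Y) if w is None else w
            theta_new = _profile_theta(Y + 0.0, res["mu"], w_eff)
            if np.all(np.abs(np.log(theta_new) - np.log(theta)) < 1e-3):
                theta = theta_new
                break
            theta = theta_new
        res = _pql_fit_matrix(
            Y, design, "nb", theta=theta, weights=w, offset=offset, fix_sigma_b2=fix_sigma_b2
        )
        res["theta"] = theta
    else:
        theta = None
        if family.family == "nb":
            theta = np.full(G, float(family.theta))
        res = _pql_fit_matrix(
            Y,
            design,
            family.family,
            theta=theta,
            weights=w,
            offset=offset,
            fix_sigma_b2=fix_sigma_b2,
        )
        res["theta"] = theta
    res["failed"] = failed
    return res


def fit_null_glmm(
    y,
    design: CellDesign,
    family: FamilySpec,
    weights=None,
    offset=None,
    fix_sigma_b2=None,
) -> NullModelFit:
    """Fit the reduced null GLMM ``g(mu0) = alpha + B b (+ offset)`` to one gene.

    Raises :class:`NonEstimableError` for an all-zero count vector (callers
    map this to a p-value of 1).  Non-convergence is reported through the
    ``converged`` flag, never raised.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("y must be a vector; use fit_null_glmm_matrix for matrices")
    if y.size != design.n_cells:
        raise ValueError("y length does not match design")
    if not (y > 0).any():
        raise NonEstimableError("all-zero response: null model not estimable")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights <= 0) or np.any(weights > 1):
            raise ValueError("weights must lie in (0, 1]")
    res = fit_null_glmm_matrix(
        y[None, :], design, family, weights=None if weights is None else weights[None, :],
        offset=offset, fix_sigma_b2=fix_sigma_b2,
    )
    theta_hat = None if res["theta"] is None else float(res["theta"][0])
    fam = (
        family
        if family.family != "nb"
        else FamilySpec("nb", theta=theta_hat, tau=family.tau)
    )
    mu0 = res["mu"][0]
    v, phi = variance_diag(mu0, fam)
    fit = NullModelFit(
        alpha_hat=float(res["alpha"][0]),
        b_hat=res["b"][0],
        sigma_b2_hat=float(res["sigma_b2"][0]),
        mu0_hat=mu0,
        theta_hat=theta_hat,
        tau_hat=1.0,
        v_diag=v,
        phi_diag=phi,
        converged=bool(res["converged"][0]),
        n_iter=int(res["n_iter"][0]),
        family=fam,
    )
    if family.is_quasi:
        fit.tau_hat = estimate_quasi_dispersion(fit, y, family)
    return fit
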