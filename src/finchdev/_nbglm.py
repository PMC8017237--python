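"""Negative-binomial GLM fitting with log link and offsets.

A small IRLS implementation specialised for the per-gene group-factor
fits used by the stagewise differential-expression tests: 24 samples,
8 group-mean parameters, a known dispersion.  The NB2 parameterisation
is used throughout: Var(y) = mu + phi * mu^2 with dispersion phi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

_EPS = 1e-10


@dataclass
class NBFit:
    beta: np.ndarray
    cov: np.ndarray  # (X' W X)^-1 at convergence
    mu: np.ndarray
    llf: float
    converged: bool
    stabilized: bool  # ridge applied (e.g. an all-zero group)


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """NB2 log-likelihood; the Poisson limit is used for tiny phi."""
    mu = np.maximum(mu, _EPS)
    if phi < 1e-12:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    r = 1.0 / phi
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: float,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> NBFit:
    """Fit an NB GLM with log link by Fisher-scoring IRLS.

    A small ridge is added when the information matrix is singular
    (e.g. a group with all-zero counts); such fits are flagged.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    # initialise from jittered observed rates
    mu = np.maximum(y, 0.5)
    eta = np.log(mu) - offset
    beta, *_ = np.linalg.lstsq(X, eta, rcond=None)
    stabilized = False
    converged = False
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = X @ beta + offset
        eta = np.clip(eta, -60.0, 60.0)
        mu = np.exp(eta)
        w = mu / (1.0 + phi * mu)  # Fisher weights for log link, NB2
        z = (eta - offset) + (y - mu) / np.maximum(mu, _EPS)
        XtW = X.T * w
        H = XtW @ X
        try:
            beta_new = np.linalg.solve(H, XtW @ z)
        except np.linalg.LinAlgError:
            stabilized = True
            H = H + 1e-6 * np.eye(p)
            beta_new = np.linalg.solve(H, XtW @ z)
        if not np.all(np.isfinite(beta_new)):
            stabilized = True
            beta_new = np.nan_to_num(beta_new, nan=0.0, posinf=30.0, neginf=-30.0)
        step = beta_new - beta
        beta = beta_new
        ll = nb_loglik(y, np.exp(np.clip(X @ beta + offset, -60, 60)), phi)
        if np.max(np.abs(step)) < tol or abs(ll - ll_old) < tol * (abs(ll_old) + 1):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    eta = np.clip(X @ beta + offset, -60.0, 60.0)
    mu = np.exp(eta)
    w = mu / (1.0 + phi * mu)
    H = (X.T * w) @ X
    if np.linalg.cond(H) > 1e12:
        stabilized = True
        H = H + 1e-6 * np.eye(p)
    cov = np.linalg.inv(H)
    return NBFit(beta=beta, cov=cov, mu=mu, llf=nb_loglik(y, mu, phi), converged=converged, stabilized=stabilized)


def dispersion_mle(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi_bounds: tuple[float, float] = (1e-6, 10.0),
    cox_reid: bool = True,
    n_refits: int = 2,
) -> float:
    """Per-gene dispersion by (adjusted) profile likelihood.

    Alternates GLM mean fits and 1-D likelihood maximisation over
    log-dispersion; the Cox-Reid adjustment -0.5 log det(X'WX) reduces
    the downward bias from estimating the group means.
    """
    y = np.asarray(y, dtype=float)
    if y.sum() == 0:
        return phi_bounds[0]
    phi = 0.1
    for _ in range(n_refits):
        fit = fit_nb_glm(y, X, offset, phi)
        mu = np.maximum(fit.mu, _EPS)

        def neg_apl(log_phi: float) -> float:
            ph = np.exp(log_phi)
            ll = nb_loglik(y, mu, ph)
            if cox_reid:
                w = mu / (1.0 + ph * mu)
                sign, logdet = np.linalg.slogdet((X.T * w) @ X)
                if sign > 0:
                    ll -= 0.5 * logdet
            return -ll

        res = optimize.minimize_scalar(
            neg_apl,
            bounds=(np.log(phi_bounds[0]), np.log(phi_bounds[1])),
            method="bounded",
            options={"xatol": 1e-4},
        )
        phi = float(np.exp(res.x))
    return phi
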