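"""Vectorized negative-binomial GLM machinery.

Fits log-link NB GLMs for many windows at once against a shared design
matrix with per-sample offsets. The NB variance is parameterized as
Var(Y) = mu + phi * mu^2, i.e. phi is the reciprocal of the shape of the
gamma mixing distribution in the gamma-Poisson representation; phi = 0 is
the Poisson limit.

All coefficients are on the natural-log scale internally.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

_ETA_MAX = 45.0  # exp(45) ~ 3.5e19, safely inside float64


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Per-window NB log-likelihood summed over samples.

    y, mu: (G, n); phi: scalar or (G,). phi=0 falls back to Poisson.
    """
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-10)
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (y.shape[0],))
    out = np.empty(y.shape[0])
    pois = phi_arr <= 0
    if np.any(pois):
        yp, mp = y[pois], mu[pois]
        out[pois] = np.sum(yp * np.log(mp) - mp - gammaln(yp + 1), axis=1)
    if np.any(~pois):
        yn, mn = y[~pois], mu[~pois]
        r = 1.0 / phi_arr[~pois][:, None]  # NB shape
        out[~pois] = np.sum(
            gammaln(yn + r) - gammaln(r) - gammaln(yn + 1)
            + yn * np.log(mn / (mn + r)) + r * np.log(r / (mn + r)),
            axis=1,
        )
    return out


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Per-window NB deviance, 2*(saturated loglik - loglik)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-10)
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (y.shape[0],))
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
    out = np.empty(y.shape[0])
    pois = phi_arr <= 0
    if np.any(pois):
        out[pois] = 2.0 * np.sum(ylogy[pois] - (y[pois] - mu[pois]), axis=1)
    if np.any(~pois):
        ph = phi_arr[~pois][:, None]
        yn, mn = y[~pois], mu[~pois]
        out[~pois] = 2.0 * np.sum(
            ylogy[~pois]
            - (yn + 1.0 / ph) * np.log((1.0 + ph * yn) / (1.0 + ph * mn)),
            axis=1,
        )
    return out


def irls_fit(y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi,
             max_iter: int = 50, tol: float = 1e-8):
    """Fit NB log-link GLMs for all windows simultaneously by IRLS.

    Parameters
    ----------
    y : (G, n) counts; X : (n, p) design; offset : (n,) or (G, n) log
    effective library sizes; phi : scalar or (G,) dispersion.

    Returns
    -------
    beta : (G, p) natural-log coefficients
    mu : (G, n) fitted means
    deviance : (G,)
    converged : (G,) bool
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    G, n = y.shape
    p = X.shape[1]
    offset = np.broadcast_to(np.asarray(offset, dtype=float), (G, n))
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (G,))

    # start from least squares on log(y + 0.5) - offset
    z0 = np.log(y + 0.5) - offset
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ z0.T).T  # (G, p)

    eta = np.clip(beta @ X.T + offset, -_ETA_MAX, _ETA_MAX)
    mu = np.exp(eta)
    dev = nb_deviance(y, mu, phi_arr)
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)

    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        ya, mua, oa = y[idx], mu[idx], offset[idx]
        pha = phi_arr[idx][:, None]
        W = mua / (1.0 + pha * mua)          # working weights
        z = (np.log(mua) - oa) + (ya - mua) / mua  # working response minus offset
        A = np.einsum("ni,gn,nj->gij", X, W, X)
        A += 1e-10 * np.eye(p)[None, :, :]
        b = np.einsum("ni,gn->gi", X, W * z)
        new_beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        new_eta = np.clip(new_beta @ X.T + oa, -_ETA_MAX, _ETA_MAX)
        new_mu = np.exp(new_eta)
        new_dev = nb_deviance(ya, new_mu, phi_arr[idx])

        # step-halve any window whose deviance got worse or went non-finite
        bad = ~np.isfinite(new_dev) | (new_dev > dev[idx] + 1e-6)
        halvings = 0
        while np.any(bad) and halvings < 10:
            nb_idx = np.flatnonzero(bad)
            new_beta[nb_idx] = 0.5 * (new_beta[nb_idx] + beta[idx][nb_idx])
            ne = np.clip(new_beta[nb_idx] @ X.T + oa[nb_idx], -_ETA_MAX, _ETA_MAX)
            new_eta[nb_idx] = ne
            new_mu[nb_idx] = np.exp(ne)
            new_dev[nb_idx] = nb_deviance(ya[nb_idx], new_mu[nb_idx],
                                          phi_arr[idx][nb_idx])
            bad = ~np.isfinite(new_dev) | (new_dev > dev[idx] + 1e-6)
            halvings += 1

        delta = np.abs(dev[idx] - new_dev)
        beta[idx] = new_beta
        mu[idx] = new_mu
        dev[idx] = new_dev
        done = delta < tol * (np.abs(new_dev) + 0.1)
        converged[idx[done]] = True
        active[idx[done]] = False

    return beta, mu, dev, converged


def cox_reid_apl(y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi,
                 fit=None) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood per window at dispersion phi:
    loglik at the fitted means minus 0.5*logdet(X' W X)."""
    if fit is None:
        fit = irls_fit(y, X, offset, phi)
    _, mu, _, _ = fit
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (y.shape[0],))
    ll = nb_loglik(y, mu, phi_arr)
    W = mu / (1.0 + phi_arr[:, None] * mu)
    A = np.einsum("ni,gn,nj->gij", X, W, X)
    A += 1e-10 * np.eye(X.shape[1])[None, :, :]
    sign, logdet = np.linalg.slogdet(A)
    return ll - 0.5 * logdet
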