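"""Model comparison (DIC) and out-of-sample predictive scoring.

Candidate models are compared two ways, following standard Bayesian practice
for geostatistical regression:

* **DIC** — deviance information criterion, DIC = D_bar + pD with
  D_bar the posterior mean deviance (-2 log likelihood), pD = D_bar - D_hat
  and D_hat the deviance at the posterior means of *all* sampled quantities,
  site-level coefficient fields included.  Lower is better; the plug-in over
  the full parameter set makes pD of a spatial model run into the hundreds.

* **Holdout scores** — posterior predictive draws at withheld observations
  scored by RMSPE (error of the predictive mean), the continuous ranked
  probability score (CRPS, strictly proper), and the empirical 95% interval
  coverage (PCI, percent) and width (PIW).  All scores are on the log10
  response scale, the modelling scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve, cholesky
from scipy.stats import norm

from . import gp
from .pipeline import ModelFrame

_SQRT_PI = np.sqrt(np.pi)


@dataclass(frozen=True)
class EvalSummary:
    """Deviance decomposition: DIC = D_bar + pD, pD = D_bar - D_hat."""

    D_bar: float
    D_hat: float
    pD: float
    DIC: float


@dataclass(frozen=True)
class PredictiveScores:
    """Holdout scores on the log10 response scale; pci is a percentage."""

    rmspe: float
    crps: float
    pci: float
    piw: float


# ---------------------------------------------------------------------------
# CRPS

def crps_gaussian(mu, sigma, y):
    """Closed-form CRPS of a N(mu, sigma^2) forecast against observation y.

    sigma * [z(2 Phi(z) - 1) + 2 phi(z) - 1/sqrt(pi)], z = (y - mu)/sigma.
    Smaller is better; zero only for a point mass on y.
    """
    mu, sigma, y = np.broadcast_arrays(mu, sigma, y)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    z = (np.asarray(y, float) - np.asarray(mu, float)) / sigma
    out = sigma * (z * (2.0 * norm.cdf(z) - 1.0) + 2.0 * norm.pdf(z) - 1.0 / _SQRT_PI)
    return out if out.shape else float(out)


def crps_sample(draws: np.ndarray, y) -> np.ndarray:
    """Sample-based CRPS estimator, mean|Y - y| - 0.5 mean|Y - Y'|.

    ``draws`` has shape (n_draws, n_rows) (or (n_draws,) for one row); the
    pairwise term uses the O(m log m) order-statistics identity
    sum_{i<j}(x_(j) - x_(i)) = sum_j (2j - m + 1) x_(j) (0-based).
    """
    draws = np.asarray(draws, dtype=float)
    squeeze = draws.ndim == 1
    if squeeze:
        draws = draws[:, None]
    m = draws.shape[0]
    y = np.broadcast_to(np.asarray(y, dtype=float), (draws.shape[1],))
    term1 = np.mean(np.abs(draws - y[None, :]), axis=0)
    srt = np.sort(draws, axis=0)
    coef = 2.0 * np.arange(m) - m + 1.0
    term2 = (coef[:, None] * srt).sum(axis=0) / (m * m)
    out = term1 - term2
    return float(out[0]) if squeeze else out


# ---------------------------------------------------------------------------
# DIC

def _deviance_per_draw(results, frame: ModelFrame) -> np.ndarray:
    """-2 log likelihood of ``frame`` for every retained draw (vectorized)."""
    post = results.posterior
    mu = _mean_matrix(post, frame)
    resid = frame.y[None, :] - mu
    n = frame.n_obs
    ll = (-0.5 * n * (np.log(2 * np.pi) + np.log(post.tau2))
          - 0.5 * np.einsum("ij,ij->i", resid, resid) / post.tau2)
    return -2.0 * ll


def _mean_matrix(post, frame: ModelFrame) -> np.ndarray:
    """(n_draws, n_rows) linear predictor; requires frame sites == fit sites."""
    if post.site_coeffs is not None:
        coeff_rows = post.site_coeffs[:, frame.site_index, :]
        mu = np.einsum("ij,dij->di", frame.X_svc, coeff_rows)
    else:
        mu = post.beta_mu @ frame.X_svc.T
    if frame.X_fixed.shape[1]:
        mu = mu + post.beta_fixed @ frame.X_fixed.T
    return mu


def compute_dic(results, frame: ModelFrame) -> EvalSummary:
    """DIC with the plug-in at posterior means of the full parameter set."""
    post = results.posterior
    dev = _deviance_per_draw(results, frame)
    D_bar = float(np.mean(dev))

    from .model import SamplerState  # local import avoids a cycle
    q = frame.X_svc.shape[1]
    beta_mu_hat = post.beta_mu.mean(axis=0)
    state = SamplerState(
        beta_mu=beta_mu_hat,
        beta_fixed=post.beta_fixed.mean(axis=0),
        w=(post.site_coeffs.mean(axis=0) - beta_mu_hat[None, :]
           if post.site_coeffs is not None else np.zeros((frame.n_sites, q))),
        tau2=float(post.tau2.mean()),
        phis=np.ones(q), A=np.eye(q))
    from .model import log_likelihood
    D_hat = -2.0 * log_likelihood(frame, state)
    pD = D_bar - D_hat
    return EvalSummary(D_bar=D_bar, D_hat=D_hat, pD=pD, DIC=D_bar + pD)


# ---------------------------------------------------------------------------
# posterior prediction

def posterior_predict(results, holdout: ModelFrame, rng=None) -> np.ndarray:
    """Composition-sampled predictive draws, shape (n_draws, n_holdout).

    For each retained posterior draw, holdout rows at lakes seen in training
    use that draw's sampled site coefficients; rows at new lakes draw their
    coefficients from the Gaussian-process conditional (kriging) given the
    training field under that draw's covariance parameters, reverting to
    beta_mu with full marginal variance far from any training lake.  Then
    y* ~ N(linear predictor, tau2).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    post = results.posterior
    frame = results.frame
    nd = post.n_draws
    nh = holdout.n_obs

    if post.site_coeffs is None:
        mu = post.beta_mu @ holdout.X_svc.T
        if holdout.X_fixed.shape[1]:
            mu = mu + post.beta_fixed @ holdout.X_fixed.T
        return mu + np.sqrt(post.tau2)[:, None] * rng.standard_normal((nd, nh))

    q = frame.X_svc.shape[1]
    train_pos = {lid: i for i, lid in enumerate(frame.site_ids)}
    site_map = np.array([train_pos.get(lid, -1) for lid in holdout.site_ids])
    new_sites = np.flatnonzero(site_map < 0)

    # coefficients at each holdout site, per draw
    coeffs = np.empty((nd, holdout.n_sites, q))
    obs = np.flatnonzero(site_map >= 0)
    coeffs[:, obs, :] = post.site_coeffs[:, site_map[obs], :]
    if new_sites.size:
        coeffs[:, new_sites, :] = _krige_new_sites(
            post, frame, holdout.sites[new_sites], rng)

    coeff_rows = coeffs[:, holdout.site_index, :]
    mu = np.einsum("ij,dij->di", holdout.X_svc, coeff_rows)
    if holdout.X_fixed.shape[1]:
        mu = mu + post.beta_fixed @ holdout.X_fixed.T
    return mu + np.sqrt(post.tau2)[:, None] * rng.standard_normal((nd, nh))


def _krige_new_sites(post, frame, new_coords, rng) -> np.ndarray:
    """Per-draw joint conditional draw of coefficient fields at unseen sites."""
    nd = post.n_draws
    ns, q = frame.n_sites, frame.X_svc.shape[1]
    m = len(new_coords)
    D_tt = gp.distance_matrix(frame.sites)
    D_nt = gp.cross_distance_matrix(new_coords, frame.sites)
    D_nn = gp.distance_matrix(new_coords)
    tril = np.tril_indices(q)
    out = np.empty((nd, m, q))
    for d in range(nd):
        A = np.zeros((q, q))
        A[tril] = post.A_elements[d]
        phis = post.phis[d]
        params = gp.LMCParams(A=A, phis=phis)
        S_tt = gp.lmc_covariance(frame.sites, params, dists=D_tt)
        S_nt = np.zeros((m * q, ns * q))
        S_nn = np.zeros((m * q, m * q))
        for j in range(q):
            a = A[:, j]
            S_nt += np.kron(np.outer(a, a), np.exp(-phis[j] * D_nt))
            S_nn += np.kron(np.outer(a, a), np.exp(-phis[j] * D_nn))
        L = cholesky(S_tt, lower=True)
        w_train = (post.site_coeffs[d] - post.beta_mu[d][None, :]).T.ravel()
        solved = cho_solve((L, True), w_train)
        mean = S_nt @ solved
        cov = S_nn - S_nt @ cho_solve((L, True), S_nt.T)
        cov[np.diag_indices_from(cov)] += 1e-10 * max(np.mean(np.diag(S_nn)), 1.0)
        Lc = cholesky(cov, lower=True)
        w_new = mean + Lc @ rng.standard_normal(m * q)
        out[d] = np.repeat(post.beta_mu[d], m).reshape(q, m).T + w_new.reshape(q, m).T
    return out


# ---------------------------------------------------------------------------
# holdout scoring

def score_holdout(draws: np.ndarray, y_obs, interval: float = 0.95) -> PredictiveScores:
    """Summarize predictive draws against holdout observations.

    RMSPE over predictive means, mean sample-based CRPS, percent of
    observations inside their central ``interval`` (equal-tailed) predictive
    interval, and the mean width of those intervals.
    """
    draws = np.asarray(draws, dtype=float)
    y_obs = np.asarray(y_obs, dtype=float)
    if draws.shape[0] < 100:
        raise ValueError("need at least 100 predictive draws per row")
    mean = draws.mean(axis=0)
    rmspe = float(np.sqrt(np.mean((mean - y_obs) ** 2)))
    crps = float(np.mean(crps_sample(draws, y_obs)))
    alpha = (1.0 - interval) / 2.0
    lo = np.quantile(draws, alpha, axis=0)
    hi = np.quantile(draws, 1.0 - alpha, axis=0)
    pci = float(100.0 * np.mean((y_obs >= lo) & (y_obs <= hi)))
    piw = float(np.mean(hi - lo))
    return PredictiveScores(rmspe=rmspe, crps=crps, pci=pci, piw=piw)


def scores_table(scores_by_model: dict) -> "pd.DataFrame":
    """Metrics-by-models table (rows RMSPE/CRPS/PCI/PIW, columns models)."""
    import pandas as pd
    return pd.DataFrame(
        {name: {"RMSPE": s.rmspe, "CRPS": s.crps, "95% PCI": s.pci,
                "95% PIW": s.piw}
         for name, s in scores_by_model.items()})
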