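"""Metropolis-within-Gibbs MCMC for spatially-varying coefficient regression.

The model for log10 chlorophyll y_t(s) at lake location s and sample time t is

    y_t(s) = xt~(s)' bt~(s) + xt(s)' b + e_t(s),    e_t(s) ~ N(0, tau2),

where xt~(s) = (1, log10 TP, log10 color)' carries the spatially-varying
coefficients bt~(s), and xt(s) any space-invariant covariates with global
coefficients b.  The coefficient fields follow a multivariate Gaussian process
bt~(s) ~ MVGP(beta_mu, Sigma(theta)) whose cross-covariance Sigma(theta) is a
Linear Model of Coregionalization (see :mod:`svclake.gp`): per-coefficient
exponential decay rates phi and a lower-triangular coregionalization matrix A.

Internally the fields are parameterized as deviations w(s) = bt~(s) - beta_mu
with a zero-mean MVGP prior, which makes the (beta_mu, b) block conjugate;
reported site coefficients are always beta_mu + w(s).

One MCMC iteration performs four blocks:

1. Gibbs: (beta_mu, b) from the exact conditional Gaussian.
2. Gibbs: the stacked deviation field w from its conditional Gaussian
   (GP prior precision plus per-site data precision).
3. Gibbs: tau2 from its inverse-gamma conditional.
4. Metropolis: random-walk updates of log phi (one block) and of A
   (log-diagonal, raw off-diagonal; one block), conditional on w, with
   Robbins-Monro step-size adaptation during burn-in targeting ~0.35
   acceptance.

The non-spatial candidate model (plain Bayesian linear regression of the same
response on the same covariates) is the special case with no coefficient
fields and is fit by :class:`NonSpatialModel` with Gibbs blocks 1 and 3 only.

Both models expose a statsmodels-like interface::

    res = SVCModel(frame).fit(n_iter=6000, n_burn=3000, seed=1)
    print(res.summary())
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular

from . import gp
from .pipeline import ModelFrame

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative, scale-aware priors.

    beta_mu and b: N(0, ``beta_var``) per element.  tau2: inverse-gamma
    (``tau2_shape``, ``tau2_scale``).  phi_j: Uniform on ``phi_bounds``; when
    None the bounds are set from the data as (-ln .05 / d95, -ln .05 / d5)
    with d5/d95 the 5th/95th percentiles of inter-site distance, i.e.
    effective ranges spanning the resolvable distances.  Diagonal elements of
    A: half-Normal(``a_diag_scale``); off-diagonal: N(0, ``a_offdiag_scale``).
    """

    beta_var: float = 1e4
    tau2_shape: float = 2.0
    tau2_scale: float = 0.1
    phi_bounds: tuple[float, float] | None = None
    a_diag_scale: float = 1.0
    a_offdiag_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.tau2_shape > 0:
            raise ValueError("tau2 shape must be positive")
        if self.phi_bounds is not None:
            lo, hi = self.phi_bounds
            if not (0 < lo < hi):
                raise ValueError("phi bounds must be positive with lower < upper")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain length and proposal controls.

    Defaults (25,000 iterations, 15,000 burn-in, thin 10) suit a final
    analysis; tests and examples use much shorter chains.
    """

    n_iter: int = 25_000
    n_burn: int = 15_000
    n_thin: int = 10
    seed: int | None = None
    phi_step: float = 0.5
    a_step: float = 0.15
    adapt: bool = True
    target_accept: float = 0.35

    def __post_init__(self) -> None:
        if not self.n_burn < self.n_iter:
            raise ValueError("n_burn must be below n_iter")
        if self.n_thin < 1:
            raise ValueError("thinning must be >= 1")


@dataclass(frozen=True)
class SVCModelSpec:
    """Which coefficients vary spatially, priors, and MCMC controls."""

    svc_terms: tuple = ("intercept", "log_tp", "log_color")
    fixed_terms: tuple | None = None  # None: all columns of frame.X_fixed
    priors: PriorConfig = field(default_factory=PriorConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)

    def __post_init__(self) -> None:
        if len(self.svc_terms) == 0:
            raise ValueError("svc_terms must be nonempty")


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in chains.

    ``site_coeffs[d, s, :]`` holds the q site-level coefficients
    beta_mu + w(s) of draw d at site s (None for the non-spatial model).
    ``A_elements`` stores the lower triangle of A row-major:
    (0,0), (1,0), (1,1), (2,0), (2,1), (2,2).
    """

    beta_mu: np.ndarray
    beta_fixed: np.ndarray
    tau2: np.ndarray
    phis: np.ndarray | None
    A_elements: np.ndarray | None
    site_coeffs: np.ndarray | None
    log_likelihood: np.ndarray
    acceptance_rates: dict
    svc_names: tuple = ()
    fixed_names: tuple = ()

    @property
    def n_draws(self) -> int:
        return len(self.tau2)


# ---------------------------------------------------------------------------
# sampler state and update blocks (exposed for unit testing)

@dataclass
class SamplerState:
    """Current values of all unknowns plus the cached GP Cholesky factor."""

    beta_mu: np.ndarray          # (q,)
    beta_fixed: np.ndarray       # (p,)
    w: np.ndarray                # (n_sites, q) deviations from beta_mu
    tau2: float
    phis: np.ndarray             # (q,)
    A: np.ndarray                # (q, q) lower triangular
    chol_sigma: np.ndarray | None = None  # lower Cholesky of Sigma(theta)
    sigma_inv: np.ndarray | None = None   # cached inverse, tied to chol_sigma

    @property
    def site_coeffs(self) -> np.ndarray:
        return self.beta_mu[None, :] + self.w


def _svc_rowterm(frame: ModelFrame, w: np.ndarray) -> np.ndarray:
    """Per-row contribution of the deviation fields, x~_i' w_{s(i)}."""
    return np.einsum("ij,ij->i", frame.X_svc, w[frame.site_index])


def _linear_predictor(frame: ModelFrame, state: SamplerState) -> np.ndarray:
    mu = frame.X_svc @ state.beta_mu + _svc_rowterm(frame, state.w)
    if frame.X_fixed.shape[1]:
        mu = mu + frame.X_fixed @ state.beta_fixed
    return mu


def log_likelihood(frame: ModelFrame, state: SamplerState) -> float:
    """Gaussian iid log-likelihood of the frame given all coefficients."""
    if not state.tau2 > 0:
        raise ValueError("tau2 must be positive")
    resid = frame.y - _linear_predictor(frame, state)
    n = frame.n_obs
    return float(-0.5 * n * (_LOG2PI + np.log(state.tau2))
                 - 0.5 * (resid @ resid) / state.tau2)


def marginal_log_likelihood(frame: ModelFrame, state: SamplerState) -> float:
    """Gaussian log-likelihood with the coefficient fields integrated out.

    y ~ N(Z gamma, B Sigma(theta) B' + tau2 I), where B expands the stacked
    site fields to rows.  Useful for comparing spatial structure between
    fits without rewarding the overfit of unconstrained site effects.
    """
    Z = np.hstack([frame.X_svc, frame.X_fixed])
    gamma = np.concatenate([state.beta_mu, state.beta_fixed])
    resid = frame.y - Z @ gamma
    n = frame.n_obs
    q = frame.X_svc.shape[1]
    D = gp.distance_matrix(frame.sites)
    M = np.zeros((n, n))
    for m in range(q):
        a = state.A[:, m]
        F = frame.X_svc @ a
        R = np.exp(-state.phis[m] * D)
        M += np.outer(F, F) * R[frame.site_index][:, frame.site_index]
    M[np.diag_indices(n)] += state.tau2
    L = np.linalg.cholesky(M)
    u = solve_triangular(L, resid, lower=True)
    return float(-0.5 * (n * _LOG2PI + u @ u) - np.log(np.diag(L)).sum())


def gibbs_update_fixed_beta(
    frame: ModelFrame, state: SamplerState, priors: PriorConfig,
    rng: np.random.Generator,
) -> SamplerState:
    """Joint conjugate draw of (beta_mu, beta_fixed).

    With vague priors and no spatial deviations, the conditional mean is the
    least-squares solution of the full design.
    """
    Z = np.hstack([frame.X_svc, frame.X_fixed])
    ytil = frame.y - _svc_rowterm(frame, state.w)
    prec = Z.T @ Z / state.tau2 + np.eye(Z.shape[1]) / priors.beta_var
    mean_rhs = Z.T @ ytil / state.tau2
    try:
        L = cholesky(prec, lower=True)
    except np.linalg.LinAlgError:
        resid_rank = np.linalg.matrix_rank(Z)
        raise np.linalg.LinAlgError(
            f"singular design: rank {resid_rank} < {Z.shape[1]} columns "
            f"{frame.svc_names + frame.fixed_names}"
        )
    mean = cho_solve((L, True), mean_rhs)
    draw = mean + solve_triangular(L, rng.standard_normal(Z.shape[1]),
                                   lower=True, trans="T")
    q = frame.X_svc.shape[1]
    state.beta_mu = draw[:q]
    state.beta_fixed = draw[q:]
    return state


def gibbs_update_site_coeffs(
    frame: ModelFrame, state: SamplerState, rng: np.random.Generator,
    site_gram: np.ndarray | None = None,
) -> SamplerState:
    """Joint conditional Gaussian draw of the stacked deviation field.

    Posterior precision = Sigma(theta)^-1 + data precision; the data term is
    the per-site Gram matrix of the spatially-varying design over tau2.
    Requires ``state.chol_sigma`` (cached from the last theta update).
    """
    ns, q = state.w.shape
    if site_gram is None:
        site_gram = _site_gram(frame)
    if state.sigma_inv is None:
        state.sigma_inv = _inv_from_chol(state.chol_sigma)
    prec = state.sigma_inv.copy()
    ar = np.arange(ns)
    r = frame.y - frame.X_svc @ state.beta_mu
    if frame.X_fixed.shape[1]:
        r = r - frame.X_fixed @ state.beta_fixed
    b = np.zeros((ns, q))
    np.add.at(b, frame.site_index, frame.X_svc * r[:, None])
    for j in range(q):
        for k in range(q):
            prec[j * ns + ar, k * ns + ar] += site_gram[:, j, k] / state.tau2
    Lp = cholesky(prec, lower=True)
    mean = cho_solve((Lp, True), (b / state.tau2).T.ravel())
    draw = mean + solve_triangular(Lp, rng.standard_normal(ns * q),
                                   lower=True, trans="T")
    state.w = draw.reshape(q, ns).T
    return state


def _inv_from_chol(L: np.ndarray) -> np.ndarray:
    """Symmetric inverse from a lower Cholesky factor (LAPACK dpotri)."""
    from scipy.linalg.lapack import dpotri
    inv, info = dpotri(L, lower=1)
    if info != 0:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError("dpotri failed")
    inv = np.tril(inv) + np.tril(inv, -1).T
    return inv


def _site_gram(frame: ModelFrame) -> np.ndarray:
    """(n_sites, q, q) per-site Gram of the spatially-varying design."""
    q = frame.X_svc.shape[1]
    G = np.zeros((frame.n_sites, q, q))
    outer = frame.X_svc[:, :, None] * frame.X_svc[:, None, :]
    np.add.at(G, frame.site_index, outer)
    return G


def gibbs_update_tau2(
    frame: ModelFrame, state: SamplerState, priors: PriorConfig,
    rng: np.random.Generator,
) -> SamplerState:
    """Inverse-gamma draw with shape + n/2 and scale + SSR/2."""
    resid = frame.y - _linear_predictor(frame, state)
    shape = priors.tau2_shape + 0.5 * frame.n_obs
    scale = priors.tau2_scale + 0.5 * (resid @ resid)
    state.tau2 = scale / rng.gamma(shape)
    return state


def _tril_indices(q):
    return np.tril_indices(q)


def _theta_log_prior(A, priors):
    lp = -0.5 * np.sum(np.diag(A) ** 2) / priors.a_diag_scale**2
    off = A[np.tril_indices_from(A, -1)]
    return lp - 0.5 * np.sum(off**2) / priors.a_offdiag_scale**2


def _theta_log_target(w_stacked, sites, dists, phis, A, priors, phi_bounds,
                      chol=None):
    """Log p(w | theta) + log prior(theta), with the Cholesky as by-product.

    Pass ``chol`` to reuse an already-computed factor for this theta.
    """
    if np.any(phis < phi_bounds[0]) or np.any(phis > phi_bounds[1]):
        return -np.inf, None
    if np.any(np.diag(A) <= 0):
        return -np.inf, None
    if chol is None:
        chol = gp.chol_lmc(sites, gp.LMCParams(A=A, phis=phis), dists=dists)
    lp = gp.mvn_logpdf_chol(w_stacked, chol) + _theta_log_prior(A, priors)
    return lp, chol


def metropolis_update_theta(
    frame: ModelFrame, state: SamplerState, priors: PriorConfig,
    rng: np.random.Generator,
    phi_step: float = 0.5, a_step: float = 0.15,
    phi_bounds: tuple[float, float] = (1e-6, 1e6),
    dists: np.ndarray | None = None,
) -> tuple[SamplerState, bool, bool]:
    """Random-walk Metropolis on (log phi) and on A, conditional on w.

    Returns the state and the (phi, A) acceptance flags.  Proposals outside
    the prior support are auto-rejected; a zero proposal step counts as
    accepted by convention (the chain "moves" to the same point).
    """
    ns, q = state.w.shape
    w_stacked = state.w.T.ravel()
    if dists is None:
        dists = gp.distance_matrix(frame.sites)
    cur_lp, cur_L = _theta_log_target(
        w_stacked, frame.sites, dists, state.phis, state.A, priors, phi_bounds,
        chol=state.chol_sigma)

    # --- phi block (log scale; uniform prior => Jacobian sum(log phi))
    prop_phis = np.exp(np.log(state.phis) + phi_step * rng.standard_normal(q))
    new_lp, new_L = _theta_log_target(
        w_stacked, frame.sites, dists, prop_phis, state.A, priors, phi_bounds)
    log_alpha = (new_lp + np.log(prop_phis).sum()) - (cur_lp + np.log(state.phis).sum())
    accept_phi = bool(np.isfinite(new_lp) and np.log(rng.uniform()) < log_alpha)
    if accept_phi:
        state.phis, cur_lp, cur_L = prop_phis, new_lp, new_L

    # --- A block (log-diagonal, raw off-diagonal)
    prop_A = state.A.copy()
    di = np.diag_indices(q)
    oi = np.tril_indices(q, -1)
    prop_A[di] = np.exp(np.log(prop_A[di]) + a_step * rng.standard_normal(q))
    prop_A[oi] = prop_A[oi] + a_step * rng.standard_normal(len(oi[0]))
    new_lp, new_L = _theta_log_target(
        w_stacked, frame.sites, dists, state.phis, prop_A, priors, phi_bounds)
    log_alpha = (new_lp + np.log(prop_A[di]).sum()) - (cur_lp + np.log(state.A[di]).sum())
    accept_a = bool(np.isfinite(new_lp) and np.log(rng.uniform()) < log_alpha)
    if accept_a:
        state.A, cur_lp, cur_L = prop_A, new_lp, new_L

    state.chol_sigma = cur_L
    if accept_phi or accept_a:
        state.sigma_inv = None  # stale; recomputed lazily from the new factor
    return state, accept_phi, accept_a


def default_phi_bounds(sites: np.ndarray) -> tuple[float, float]:
    """Uniform prior support for phi from the inter-site distance quantiles."""
    D = gp.distance_matrix(sites)
    d = D[np.triu_indices_from(D, 1)]
    d5, d95 = np.percentile(d[d > 0], [5, 95])
    c = -np.log(gp.EFFECTIVE_CORRELATION)
    return c / d95, c / d5


# ---------------------------------------------------------------------------
# model classes

class SVCModel:
    """Spatially-varying coefficient regression on a :class:`ModelFrame`.

    The intercept, log10-TP and log10-color coefficients follow a
    coregionalized Gaussian process over lake locations; any covariates in
    ``frame.X_fixed`` enter with global coefficients.
    """

    def __init__(self, frame: ModelFrame, priors: PriorConfig | None = None):
        self.frame = frame
        if priors is None or priors.phi_bounds is None:
            bounds = default_phi_bounds(frame.sites)
            priors = replace(priors or PriorConfig(), phi_bounds=bounds)
        self.priors = priors

    @classmethod
    def from_dataframe(cls, df, fixed_terms=(), priors=None, **frame_kw):
        from .pipeline import build_model_frame
        return cls(build_model_frame(df, fixed_terms=fixed_terms, **frame_kw),
                   priors=priors)

    def fit(self, n_iter=25_000, n_burn=15_000, n_thin=10, seed=None,
            mcmc: MCMCConfig | None = None, progress: bool = False) -> "SVCResults":
        cfg = mcmc or MCMCConfig(n_iter=n_iter, n_burn=n_burn, n_thin=n_thin,
                                 seed=seed)
        samples = run_mcmc(self.frame, SVCModelSpec(priors=self.priors, mcmc=cfg),
                           progress=progress)
        return SVCResults(self, samples)


def run_mcmc(frame: ModelFrame, spec: SVCModelSpec,
             progress: bool = False) -> PosteriorSamples:
    """Execute burn-in plus sampling for the SVC model; see module docstring.

    Fully reproducible under ``spec.mcmc.seed``.  Aborts with diagnostics if
    the chain's log-density becomes non-finite.
    """
    cfg = spec.mcmc
    priors = spec.priors
    if priors.phi_bounds is None:
        priors = replace(priors, phi_bounds=default_phi_bounds(frame.sites))
    rng = np.random.default_rng(cfg.seed)
    ns, q = frame.n_sites, frame.X_svc.shape[1]
    p = frame.X_fixed.shape[1]
    dists = gp.distance_matrix(frame.sites)
    site_gram = _site_gram(frame)

    # initialize from least squares
    Z = np.hstack([frame.X_svc, frame.X_fixed])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise np.linalg.LinAlgError(
            f"singular design over columns {frame.svc_names + frame.fixed_names}")
    coef, *_ = np.linalg.lstsq(Z, frame.y, rcond=None)
    resid = frame.y - Z @ coef
    lo, hi = priors.phi_bounds
    state = SamplerState(
        beta_mu=coef[:q].copy(),
        beta_fixed=coef[q:].copy(),
        w=np.zeros((ns, q)),
        tau2=max(float(resid @ resid) / max(frame.n_obs - Z.shape[1], 1), 1e-6),
        phis=np.full(q, np.sqrt(lo * hi)),
        A=np.diag(np.full(q, 0.2)),
    )
    state.chol_sigma = gp.chol_lmc(
        frame.sites, gp.LMCParams(A=state.A, phis=state.phis), dists=dists)

    n_keep = (cfg.n_iter - cfg.n_burn + cfg.n_thin - 1) // cfg.n_thin
    out = PosteriorSamples(
        beta_mu=np.empty((n_keep, q)),
        beta_fixed=np.empty((n_keep, p)),
        tau2=np.empty(n_keep),
        phis=np.empty((n_keep, q)),
        A_elements=np.empty((n_keep, q * (q + 1) // 2)),
        site_coeffs=np.empty((n_keep, ns, q)),
        log_likelihood=np.empty(n_keep),
        acceptance_rates={},
        svc_names=frame.svc_names,
        fixed_names=frame.fixed_names,
    )
    tril = np.tril_indices(q)
    phi_step, a_step = cfg.phi_step, cfg.a_step
    acc = {"phi": 0, "A": 0}
    kept = 0
    for it in range(cfg.n_iter):
        state = gibbs_update_fixed_beta(frame, state, priors, rng)
        state = gibbs_update_site_coeffs(frame, state, rng, site_gram=site_gram)
        state = gibbs_update_tau2(frame, state, priors, rng)
        state, a_phi, a_A = metropolis_update_theta(
            frame, state, priors, rng, phi_step=phi_step, a_step=a_step,
            phi_bounds=priors.phi_bounds, dists=dists)
        acc["phi"] += a_phi
        acc["A"] += a_A
        if cfg.adapt and it < cfg.n_burn:
            eta = (it + 1) ** -0.6
            phi_step *= np.exp(eta * (a_phi - cfg.target_accept))
            a_step *= np.exp(eta * (a_A - cfg.target_accept))
        if it >= cfg.n_burn and (it - cfg.n_burn) % cfg.n_thin == 0:
            ll = log_likelihood(frame, state)
            if not np.isfinite(ll):
                raise RuntimeError(
                    f"divergent chain at iteration {it}: log-likelihood {ll}, "
                    f"tau2 {state.tau2}, phis {state.phis}"
                )
            out.beta_mu[kept] = state.beta_mu
            out.beta_fixed[kept] = state.beta_fixed
            out.tau2[kept] = state.tau2
            out.phis[kept] = state.phis
            out.A_elements[kept] = state.A[tril]
            out.site_coeffs[kept] = state.site_coeffs
            out.log_likelihood[kept] = ll
            kept += 1
        if progress and (it + 1) % max(cfg.n_iter // 10, 1) == 0:
            logger.info("iteration %d/%d", it + 1, cfg.n_iter)
    out.acceptance_rates = {k: v / cfg.n_iter for k, v in acc.items()}
    return out


class NonSpatialModel:
    """Bayesian linear regression of log10 CHL on the same covariates.

    The non-spatial candidate model: intercept, log10 TP and log10 color (and
    any fixed covariates) all carry global, space-invariant coefficients.
    Fit by Gibbs sampling on (coefficients, tau2) with vague priors, so
    posterior coefficient means approach the least-squares estimates.
    """

    def __init__(self, frame: ModelFrame, priors: PriorConfig | None = None):
        self.frame = frame
        self.priors = priors or PriorConfig()

    def fit(self, n_iter=5000, n_burn=1000, n_thin=1, seed=None) -> "SVCResults":
        frame, priors = self.frame, self.priors
        rng = np.random.default_rng(seed)
        Z = np.hstack([frame.X_svc, frame.X_fixed])
        q, p = frame.X_svc.shape[1], frame.X_fixed.shape[1]
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise np.linalg.LinAlgError(
                f"singular design over columns {frame.svc_names + frame.fixed_names}")
        coef, *_ = np.linalg.lstsq(Z, frame.y, rcond=None)
        resid = frame.y - Z @ coef
        state = SamplerState(
            beta_mu=coef[:q].copy(), beta_fixed=coef[q:].copy(),
            w=np.zeros((frame.n_sites, q)),
            tau2=max(float(resid @ resid) / max(frame.n_obs - Z.shape[1], 1), 1e-6),
            phis=np.ones(q), A=np.eye(q))
        n_keep = (n_iter - n_burn + n_thin - 1) // n_thin
        out = PosteriorSamples(
            beta_mu=np.empty((n_keep, q)), beta_fixed=np.empty((n_keep, p)),
            tau2=np.empty(n_keep), phis=None, A_elements=None, site_coeffs=None,
            log_likelihood=np.empty(n_keep), acceptance_rates={},
            svc_names=frame.svc_names, fixed_names=frame.fixed_names)
        kept = 0
        for it in range(n_iter):
            state = gibbs_update_fixed_beta(frame, state, priors, rng)
            state = gibbs_update_tau2(frame, state, priors, rng)
            if it >= n_burn and (it - n_burn) % n_thin == 0:
                out.beta_mu[kept] = state.beta_mu
                out.beta_fixed[kept] = state.beta_fixed
                out.tau2[kept] = state.tau2
                out.log_likelihood[kept] = log_likelihood(frame, state)
                kept += 1
        return SVCResults(self, out)


def fit_nonspatial(frame: ModelFrame, n_iter=5000, n_burn=1000, n_thin=1,
                   seed=None, priors=None) -> "SVCResults":
    """Convenience wrapper: fit the non-spatial candidate model."""
    return NonSpatialModel(frame, priors=priors).fit(
        n_iter=n_iter, n_burn=n_burn, n_thin=n_thin, seed=seed)


class SVCResults:
    """Posterior summaries, diagnostics, prediction and scoring.

    Thin result object shared by :class:`SVCModel` and
    :class:`NonSpatialModel`; heavy lifting lives in :mod:`svclake.evaluate`
    and :mod:`svclake.summaries`.
    """

    def __init__(self, model, posterior: PosteriorSamples):
        self.model = model
        self.frame: ModelFrame = model.frame
        self.posterior = posterior

    @property
    def is_spatial(self) -> bool:
        return self.posterior.site_coeffs is not None

    # -- parameter summaries -------------------------------------------------

    def params_table(self) -> "pd.DataFrame":
        """Posterior mean, sd and central 95% interval per scalar parameter."""
        import pandas as pd
        post = self.posterior
        rows = {}
        for name, draws in self._scalar_chains().items():
            rows[name] = {
                "mean": np.mean(draws), "sd": np.std(draws, ddof=1),
                "q2.5": np.quantile(draws, 0.025),
                "q97.5": np.quantile(draws, 0.975),
            }
        return pd.DataFrame(rows).T

    def _scalar_chains(self) -> dict:
        post = self.posterior
        chains = {}
        for j, name in enumerate(post.svc_names):
            chains[f"beta_mu[{name}]"] = post.beta_mu[:, j]
        for j, name in enumerate(post.fixed_names):
            chains[f"beta[{name}]"] = post.beta_fixed[:, j]
        chains["tau2"] = post.tau2
        if post.phis is not None:
            for j, name in enumerate(post.svc_names):
                chains[f"eff_range[{name}]"] = gp._RANGE_FACTOR / post.phis[:, j]
        return chains

    def effective_ranges(self) -> dict:
        """Posterior median effective range (km) per coefficient process."""
        post = self.posterior
        if post.phis is None:
            return {}
        return {
            name: float(np.median(gp._RANGE_FACTOR / post.phis[:, j]))
            for j, name in enumerate(post.svc_names)
        }

    def rhat(self) -> dict:
        """Split-chain potential scale reduction per scalar parameter."""
        import arviz as az
        out = {}
        for name, draws in self._scalar_chains().items():
            n = len(draws) // 2 * 2
            out[name] = float(az.rhat(draws[:n].reshape(2, -1)))
        return out

    # -- downstream ----------------------------------------------------------

    def dic(self, frame: ModelFrame | None = None):
        from .evaluate import compute_dic
        return compute_dic(self, frame or self.frame)

    def predict(self, holdout: ModelFrame, rng=None) -> np.ndarray:
        from .evaluate import posterior_predict
        return posterior_predict(self, holdout, rng=rng)

    def score(self, holdout: ModelFrame, rng=None):
        from .evaluate import score_holdout
        return score_holdout(self.predict(holdout, rng=rng), holdout.y)

    def coefficient_field(self, prob: float = 0.95):
        from .summaries import coefficient_field
        return coefficient_field(self, prob=prob)

    def summary(self) -> str:
        post = self.posterior
        kind = "SVC" if self.is_spatial else "non-spatial"
        lines = [
            f"{kind} chlorophyll model | n_obs={self.frame.n_obs} "
            f"n_sites={self.frame.n_sites} draws={post.n_draws}",
            "",
            self.params_table().round(4).to_string(),
        ]
        if self.is_spatial:
            acc = ", ".join(f"{k}={v:.2f}" for k, v in post.acceptance_rates.items())
            lines += ["", f"Metropolis acceptance: {acc}"]
        return "\n".join(lines)
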