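"""Spatial correlation, effective range, and the coregionalized Gaussian process prior.

The spatially-varying coefficient model places a multivariate Gaussian process
(MVGP) prior on the stacked coefficient fields.  The cross-covariance is built
with a Linear Model of Coregionalization (LMC): for ``q`` coefficient processes
with lower-triangular coregionalization matrix ``A`` and per-process decay
rates ``phi``,

    Cov = sum_j (a_j a_j^T) kron R_j,      R_j[k, l] = rho(d_kl; phi_j),

where ``a_j`` is the j-th column of ``A`` and ``rho`` is the (exponential)
spatial correlation function.  Stacking is coefficient-major: the first block
of the ``n*q`` vector holds coefficient 1 at every site, then coefficient 2,
and so on.

Distances are planar kilometres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import brentq
from scipy.spatial.distance import cdist, pdist, squareform

#: Correlation level at which spatial dependence is declared negligible.
EFFECTIVE_CORRELATION = 0.05

#: -ln(0.05); effective range of the exponential model is this over phi.
_RANGE_FACTOR = -np.log(EFFECTIVE_CORRELATION)

_FAMILIES = ("exponential",)


@dataclass(frozen=True)
class CorrelationSpec:
    """A parametric spatial correlation function.

    Parameters
    ----------
    phi : float
        Decay rate per km; larger phi means shorter-range dependence.
    family : str
        Correlation family; only ``"exponential"`` (exp(-phi * d)) is
        implemented.  The class exists as the extension point for Matern.
    """

    phi: float
    family: str = "exponential"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown correlation family {self.family!r}")
        if not self.phi > 0:
            raise ValueError("phi must be positive")


@dataclass(frozen=True)
class LMCParams:
    """Parameters of the Linear Model of Coregionalization.

    ``A`` is the lower-triangular q x q coregionalization matrix with positive
    diagonal (so K = A A^T is the positive-definite covariance among
    coefficients at zero distance); ``phis`` holds one decay rate per latent
    process.
    """

    A: np.ndarray
    phis: np.ndarray
    family: str = "exponential"

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        phis = np.asarray(self.phis, dtype=float)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "phis", phis)
        q = A.shape[0]
        if A.shape != (q, q):
            raise ValueError("A must be square")
        if phis.shape != (q,):
            raise ValueError("phis must have one entry per coefficient")
        if not np.allclose(A, np.tril(A)):
            raise ValueError("A must be lower triangular")
        if not np.all(np.diag(A) > 0):
            raise ValueError("diag(A) must be positive")
        if not np.all(phis > 0):
            raise ValueError("phis must be positive")

    @property
    def q(self) -> int:
        return self.A.shape[0]


def distance_matrix(sites: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances (km) between planar site coordinates."""
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    if sites.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(sites))


def cross_distance_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distances (km) between two site sets, shape (len(a), len(b))."""
    return cdist(np.atleast_2d(a), np.atleast_2d(b))


def correlation(d, spec: CorrelationSpec | float) -> np.ndarray:
    """Spatial correlation at distance ``d`` (km).

    Equals 1 at d = 0 and decays monotonically; exponential family:
    exp(-phi * d).
    """
    phi = spec.phi if isinstance(spec, CorrelationSpec) else float(spec)
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    return np.exp(-phi * d)


def effective_range(spec: CorrelationSpec | float) -> float:
    """Distance at which spatial correlation drops to 0.05.

    For the exponential family this is -ln(0.05)/phi (about 3/phi).  For any
    other monotone family the equation correlation(d) = 0.05 is solved by
    bracketing and bisection.
    """
    if not isinstance(spec, CorrelationSpec):
        spec = CorrelationSpec(phi=float(spec))
    if spec.family == "exponential":
        return _RANGE_FACTOR / spec.phi
    # Generic monotone fallback: bracket then root-find.
    hi = 1.0
    while correlation(hi, spec) > EFFECTIVE_CORRELATION:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("correlation does not decay to 0.05")
    return brentq(lambda d: correlation(d, spec) - EFFECTIVE_CORRELATION, 0.0, hi)


def phi_for_range(range_km: float) -> float:
    """Exponential decay rate whose effective range is ``range_km``."""
    if not range_km > 0:
        raise ValueError("range must be positive")
    return _RANGE_FACTOR / range_km


def lmc_covariance(
    sites: np.ndarray,
    params: LMCParams,
    jitter: float = 1e-8,
    dists: np.ndarray | None = None,
) -> np.ndarray:
    """Dense (n*q x n*q) covariance of the stacked coefficient fields.

    Coefficient-major stacking: entry (j*n + s, k*n + t) is the covariance
    between coefficient j at site s and coefficient k at site t.  A relative
    jitter (``jitter`` times the mean diagonal) is added to the diagonal to
    keep the factorization stable; pass ``jitter=0`` to disable.
    """
    D = distance_matrix(sites) if dists is None else dists
    n = D.shape[0]
    q = params.q
    cov = np.zeros((n * q, n * q))
    for j in range(q):
        a = params.A[:, j]
        R = np.exp(-params.phis[j] * D)
        cov += np.kron(np.outer(a, a), R)
    if jitter:
        cov[np.diag_indices_from(cov)] += jitter * np.mean(np.diag(cov))
    return cov


def chol_lmc(sites, params, jitter=1e-8, dists=None) -> np.ndarray:
    """Lower Cholesky factor of :func:`lmc_covariance`.

    Raises a ``LinAlgError`` with advice if the matrix is numerically singular
    even after jitter (usually duplicated site coordinates).
    """
    cov = lmc_covariance(sites, params, jitter=jitter, dists=dists)
    try:
        return cholesky(cov, lower=True)
    except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            "LMC covariance is not positive definite after jitter; "
            "de-duplicate or jitter coincident sites"
        ) from err


def sample_mvgp(
    sites: np.ndarray,
    params: LMCParams,
    mean: np.ndarray,
    rng: np.random.Generator,
    jitter: float = 1e-8,
) -> np.ndarray:
    """One draw of the coefficient fields, returned as an (n_sites, q) array.

    Row s holds the q coefficients at site s; the stacked vector has
    distribution N(mean kron 1, lmc_covariance).
    """
    sites = np.atleast_2d(sites)
    n = sites.shape[0]
    q = params.q
    mean = np.asarray(mean, dtype=float)
    L = chol_lmc(sites, params, jitter=jitter)
    z = rng.standard_normal(n * q)
    stacked = np.repeat(mean, n) + L @ z
    return stacked.reshape(q, n).T


def mvn_logpdf_chol(x: np.ndarray, L: np.ndarray) -> float:
    """Log-density of N(0, L L^T) at ``x`` given the lower Cholesky factor."""
    u = solve_triangular(L, x, lower=True)
    return -0.5 * (x.size * np.log(2.0 * np.pi) + u @ u) - np.log(np.diag(L)).sum()
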