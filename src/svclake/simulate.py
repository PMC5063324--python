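"""Synthetic lake datasets with the statistical structure the models assume.

The generator forward-simulates the spatially-varying coefficient model:
lake locations scattered over a planar extent, coefficient fields drawn from
the coregionalized Gaussian process, right-skewed (log-normal) water-chemistry
and geomorphology covariates calibrated to the study population's medians,
repeated sampling for a minority of lakes, and log10-scale Gaussian residual
noise.  Every generating parameter and latent field is kept in a truth record
so parameter recovery and residual-based oracles are exact.

Defaults are the study conditions: mean coefficients (-0.36, 0.698, -0.02)
for (intercept, log10 TP, log10 color), residual variance 0.63, effective
spatial ranges (32.56, 26.32, 216.05) km on a 300 x 300 km extent, TP and
color medians of 14 (ug/L, PCU), ~27% of lakes resampled with on the order of
30 observations, and a 72% drainage fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import gp

_DEFAULT_RANGES = (32.56, 26.32, 216.05)  # km: intercept, TP, color


def _default_phis():
    return tuple(gp.phi_for_range(r) for r in _DEFAULT_RANGES)


def _default_A():
    # Coefficient-field scales chosen from the reported across-lake spread:
    # TP slopes spanning ~0.27-1.38 (sd ~0.2), a handful of color slopes at
    # +-0.3, and a wider intercept field; mild intercept-TP cross-correlation.
    return ((0.35, 0.0, 0.0),
            (0.10, 0.18, 0.0),
            (0.0, 0.0, 0.12))


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters; defaults emulate the study population."""

    n_sites: int = 150
    extent: tuple[float, float] = (300.0, 300.0)
    phis: tuple = field(default_factory=_default_phis)
    A_true: tuple = field(default_factory=_default_A)
    beta_mu_true: tuple = (-0.36, 0.698, -0.02)
    beta_fixed_true: tuple = (-0.13, 0.02, 0.45, 0.16, 0.21)
    fixed_terms: tuple = ("log_max_depth", "log_calk", "prop_agriculture",
                          "prop_wetland", "drainage")
    tau2_true: float = 0.63
    # log10-scale medians and sds of the log-normal covariates
    log_tp_median: float = np.log10(14.0)
    log_tp_sd: float = 0.35
    log_color_median: float = np.log10(14.0)
    log_color_sd: float = 0.35
    log_depth_median: float = np.log10(9.2)
    log_depth_sd: float = 0.25
    log_area_median: float = np.log10(55.49)
    log_area_sd: float = 0.5
    log_calk_median: float = np.log10(10.06)
    log_calk_sd: float = 0.5
    obs_log_sd: float = 0.15          # within-lake log10 TP/color variation
    drainage_prob: float = 606 / 838
    repeat_fraction: float = 228 / 838
    repeat_mean_extra: float = 29.0   # Poisson mean of extra samples
    min_separation: float = 0.0       # km; 0 disables thinning
    year_range: tuple[int, int] = (1986, 2013)

    def __post_init__(self) -> None:
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise ValueError("extent must be nonempty")
        if self.tau2_true < 0:
            raise ValueError("variances must be nonnegative")

    @property
    def lmc_params(self) -> gp.LMCParams:
        return gp.LMCParams(A=np.asarray(self.A_true, dtype=float),
                            phis=np.asarray(self.phis, dtype=float))


@dataclass
class SimTruth:
    """Everything needed to reconstruct the noiseless linear predictor."""

    config: SimConfig
    sites: np.ndarray
    site_ids: np.ndarray
    coeff_fields: np.ndarray       # (n_sites, 3): intercept, TP, color
    beta_fixed: np.ndarray
    row_site: np.ndarray           # row -> site position
    linear_predictor: np.ndarray   # noiseless log10 CHL per row
    noise: np.ndarray              # realized residuals per row

    def to_json(self, path) -> None:
        payload = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.config).items()},
            "sites": self.sites.tolist(),
            "site_ids": list(map(str, self.site_ids)),
            "coeff_fields": self.coeff_fields.tolist(),
            "beta_fixed": self.beta_fixed.tolist(),
            "row_site": self.row_site.tolist(),
            "linear_predictor": self.linear_predictor.tolist(),
            "noise": self.noise.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def generate_sites(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform random lake locations, optionally thinned to a minimum spacing."""
    if cfg.n_sites < 1:
        raise ValueError("need at least one site")
    w, h = cfg.extent
    if cfg.min_separation <= 0:
        return rng.uniform((0, 0), (w, h), size=(cfg.n_sites, 2))
    sites = []
    for _ in range(200 * cfg.n_sites):
        cand = rng.uniform((0, 0), (w, h))
        if all(np.hypot(*(cand - s)) >= cfg.min_separation for s in sites):
            sites.append(cand)
            if len(sites) == cfg.n_sites:
                return np.array(sites)
    raise RuntimeError(
        f"could not place {cfg.n_sites} sites {cfg.min_separation} km apart")


def _summer_dates(n, cfg, rng):
    years = rng.integers(cfg.year_range[0], cfg.year_range[1] + 1, size=n)
    offsets = rng.integers(0, 93, size=n)  # Jun 15 .. Sep 15 inclusive
    base = pd.to_datetime({"year": years, "month": 6, "day": 15})
    return base + pd.to_timedelta(offsets, unit="D")


def generate_dataset(cfg: SimConfig | None = None, rng=None):
    """Forward-simulate an observation table; returns (DataFrame, SimTruth).

    The response is assembled on the log10 scale from the sampled coefficient
    fields, fixed effects and N(0, tau2) noise, then back-transformed to
    natural units so the table round-trips through the data pipeline.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sites = generate_sites(cfg, rng)
    ns = cfg.n_sites
    site_ids = np.array([f"lake{i:04d}" for i in range(ns)])

    A = np.asarray(cfg.A_true, dtype=float)
    if np.all(np.diag(A) > 0):
        fields = gp.sample_mvgp(sites, cfg.lmc_params, cfg.beta_mu_true, rng)
    else:  # degenerate no-variation case: fields pinned at the mean
        fields = np.tile(np.asarray(cfg.beta_mu_true, float), (ns, 1))

    # lake-level attributes
    log_tp_lake = rng.normal(cfg.log_tp_median, cfg.log_tp_sd, ns)
    log_color_lake = rng.normal(cfg.log_color_median, cfg.log_color_sd, ns)
    max_depth = 10 ** rng.normal(cfg.log_depth_median, cfg.log_depth_sd, ns)
    lake_area = np.clip(10 ** rng.normal(cfg.log_area_median, cfg.log_area_sd, ns),
                        4.5, 9000.0)
    calk = 10 ** rng.normal(cfg.log_calk_median, cfg.log_calk_sd, ns)
    catchment_area = calk * lake_area
    props = rng.dirichlet(8.0 * np.array([0.17, 0.10, 0.10, 0.10, 0.53]), size=ns)
    connectivity = np.where(rng.uniform(size=ns) < cfg.drainage_prob,
                            "drainage", "isolated")

    # replicate structure: a minority of lakes gets Poisson extra samples
    n_rep = int(round(cfg.repeat_fraction * ns))
    rep_lakes = rng.choice(ns, size=n_rep, replace=False) if n_rep else np.array([], int)
    counts = np.ones(ns, dtype=int)
    counts[rep_lakes] += rng.poisson(cfg.repeat_mean_extra, size=n_rep)
    row_site = np.repeat(np.arange(ns), counts)
    n = len(row_site)

    log_tp = log_tp_lake[row_site] + rng.normal(0, cfg.obs_log_sd, n)
    log_color = log_color_lake[row_site] + rng.normal(0, cfg.obs_log_sd, n)

    X_svc = np.column_stack([np.ones(n), log_tp, log_color])
    lin = np.einsum("ij,ij->i", X_svc, fields[row_site])

    fixed_cols = {
        "log_max_depth": np.log10(max_depth)[row_site],
        "log_calk": np.log10(calk)[row_site],
        "prop_agriculture": props[:, 0][row_site],
        "prop_wetland": props[:, 2][row_site],
        "drainage": (connectivity == "drainage").astype(float)[row_site],
    }
    beta_fixed = np.asarray(cfg.beta_fixed_true, dtype=float)
    for term, b in zip(cfg.fixed_terms, beta_fixed):
        lin = lin + b * fixed_cols[term]

    noise = rng.normal(0.0, np.sqrt(cfg.tau2_true), n) if cfg.tau2_true else np.zeros(n)
    y_log = lin + noise

    df = pd.DataFrame({
        "lake_id": site_ids[row_site],
        "x": sites[row_site, 0],
        "y": sites[row_site, 1],
        "date": _summer_dates(n, cfg, rng),
        "chl": 10 ** y_log,
        "tp": 10 ** log_tp,
        "color": 10 ** log_color,
        "max_depth": max_depth[row_site],
        "lake_area": lake_area[row_site],
        "catchment_area": catchment_area[row_site],
        "prop_agriculture": props[:, 0][row_site],
        "prop_urban": props[:, 1][row_site],
        "prop_wetland": props[:, 2][row_site],
        "prop_forest": props[:, 3][row_site],
        "connectivity": connectivity[row_site],
    })
    truth = SimTruth(config=cfg, sites=sites, site_ids=site_ids,
                     coeff_fields=fields, beta_fixed=beta_fixed,
                     row_site=row_site, linear_predictor=lin, noise=noise)
    return df, truth


def generate_filter_fixture(rng=None, n_rows: int = 20):
    """Small observation table with known inclusion-rule violations.

    Returns (DataFrame, answer_key); the key counts rows dropped by each rule
    (first-failure attribution in the fixed order area, season, triplet,
    depth) plus the kept count.  Violations: one lake at exactly the 4 ha
    boundary, one oversized lake, one out-of-season sample, one missing
    color, one missing depth.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if n_rows < 6:
        raise ValueError("fixture needs at least 6 rows")
    cfg = SimConfig(n_sites=n_rows, repeat_fraction=0.0, min_separation=0.0)
    df, _ = generate_dataset(cfg, rng)
    df = df.iloc[:n_rows].reset_index(drop=True).copy()
    df.loc[0, "lake_area"] = 4.0        # boundary: "greater than 4 ha" is strict
    df.loc[1, "lake_area"] = 15_000.0
    df.loc[2, "date"] = pd.Timestamp(year=2005, month=5, day=1)
    df.loc[3, "color"] = np.nan
    df.loc[4, "max_depth"] = np.nan
    key = {"area": 2, "season": 1, "triplet": 1, "depth": 1,
           "kept": n_rows - 5}
    return df, key
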