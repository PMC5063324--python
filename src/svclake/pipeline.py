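"""Read, validate, filter, transform and partition lake observation tables.

The observation table is a flat pandas DataFrame with one row per sampling
event: lake identifier, coordinates, date, summer epilimnetic chlorophyll *a*
(ug/L), total phosphorus (ug/L), water color (PCU), lake/catchment
geomorphology, catchment land-cover proportions and hydrologic connectivity
class.  Inclusion rules mirror the study design: lakes strictly between 4 and
10,000 ha, samples between 15 June and 15 September (inclusive), chlorophyll,
phosphorus and color measured at the same sampling event, and maximum depth
known.

``build_model_frame`` produces the :class:`ModelFrame` consumed by the models:
log10 response and covariates, the spatially-varying design (intercept,
log10 TP, log10 color), a configurable fixed design, and the unique-lake site
list that indexes the Gaussian-process coefficient fields.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: Columns an observation table may carry; chl/tp/color/max_depth may be NaN.
SCHEMA = [
    "lake_id", "x", "y", "lon", "lat", "date", "chl", "tp", "color",
    "max_depth", "lake_area", "catchment_area", "prop_agriculture",
    "prop_wetland", "prop_urban", "prop_forest", "connectivity",
]

_PROPORTION_COLS = ["prop_agriculture", "prop_wetland", "prop_urban", "prop_forest"]

#: Fixed (space-invariant) covariates of the full candidate model, in order.
DEFAULT_FIXED_TERMS = (
    "log_max_depth", "log_calk", "prop_agriculture", "prop_wetland", "drainage",
)

#: Spatially-varying design columns; fixed by the model definition.
SVC_TERMS = ("intercept", "log_tp", "log_color")

EARTH_RADIUS_KM = 6371.0088


class ValidationError(ValueError):
    """An observation table violates a schema invariant."""


# ---------------------------------------------------------------------------
# reading & validation

def read_observations(path) -> pd.DataFrame:
    """Read an observation CSV (ISO-8601 dates, empty cells for missing)."""
    df = pd.read_csv(path)
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"])
    validate_observations(df)
    return df


def validate_observations(df: pd.DataFrame) -> None:
    """Raise :class:`ValidationError` on schema violations."""
    if "lake_id" not in df.columns:
        raise ValidationError("observation table must carry lake_id")
    ids = df["lake_id"].astype(str)
    if (ids.str.len() == 0).any() or df["lake_id"].isna().any():
        raise ValidationError("lake_id must be non-empty")
    for col in ("chl", "tp", "color", "max_depth"):
        if col in df.columns:
            bad = df[col].notna() & (df[col] <= 0)
            if bad.any():
                which = df.loc[bad, "lake_id"].iloc[0]
                raise ValidationError(f"{col} must be strictly positive (lake {which})")
    for col in _PROPORTION_COLS:
        if col in df.columns:
            vals = df[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise ValidationError(f"{col} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# projection

@dataclass(frozen=True)
class ConicProjection:
    """Equidistant conic projection (spherical) producing planar km.

    Distances along meridians are exact; within a few-hundred-km study extent
    pairwise Euclidean distances approximate great-circle distances to well
    under a percent when the standard parallels bracket the data.
    """

    lat0: float
    lon0: float
    lat1: float
    lat2: float
    radius_km: float = EARTH_RADIUS_KM

    @classmethod
    def for_extent(cls, lat, lon) -> "ConicProjection":
        """Projection centred on the data bounding box, standard parallels at
        the 1/6 and 5/6 latitude quantiles (conventional placement)."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        lo, hi = lat.min(), lat.max()
        span = max(hi - lo, 1e-6)
        return cls(
            lat0=0.5 * (lo + hi),
            lon0=0.5 * (lon.min() + lon.max()),
            lat1=lo + span / 6.0,
            lat2=hi - span / 6.0,
        )

    def __call__(self, lon, lat):
        lon = np.radians(np.asarray(lon, dtype=float))
        lat = np.radians(np.asarray(lat, dtype=float))
        p1, p2 = np.radians(self.lat1), np.radians(self.lat2)
        p0, l0 = np.radians(self.lat0), np.radians(self.lon0)
        if np.isclose(p1, p2):
            n = np.sin(p1)
        else:
            n = (np.cos(p1) - np.cos(p2)) / (p2 - p1)
        if np.isclose(n, 0.0):  # equatorial degenerate case: plate carree
            x = self.radius_km * (lon - l0) * np.cos(p0)
            y = self.radius_km * (lat - p0)
            return x, y
        G = np.cos(p1) / n + p1
        rho = self.radius_km * (G - lat)
        rho0 = self.radius_km * (G - p0)
        theta = n * (lon - l0)
        return rho * np.sin(theta), rho0 - rho * np.cos(theta)


def project_coordinates(df: pd.DataFrame, projection=None) -> pd.DataFrame:
    """Ensure every record carries finite planar (x, y) in km.

    ``projection=None`` uses existing planar x/y if present ("identity"),
    otherwise fits :meth:`ConicProjection.for_extent` to the lon/lat columns.
    A callable ``projection(lon, lat) -> (x, y)`` may be supplied.
    """
    df = df.copy()
    has_xy = {"x", "y"}.issubset(df.columns) and df[["x", "y"]].notna().all().all()
    if projection is None and has_xy:
        _check_finite_xy(df)
        return df
    if not {"lon", "lat"}.issubset(df.columns):
        raise ValidationError("no planar x/y and no lon/lat columns to project")
    lat = df["lat"].to_numpy(float)
    lon = df["lon"].to_numpy(float)
    bad = ~np.isfinite(lat) | ~np.isfinite(lon) | (np.abs(lat) > 90) | (np.abs(lon) > 360)
    if bad.any():
        raise ValidationError(
            f"coordinates outside projection validity for lake "
            f"{df.loc[bad, 'lake_id'].iloc[0]}"
        )
    if projection is None:
        projection = ConicProjection.for_extent(lat, lon)
    x, y = projection(lon, lat)
    df["x"], df["y"] = x, y
    _check_finite_xy(df)
    return df


def _check_finite_xy(df: pd.DataFrame) -> None:
    bad = ~np.isfinite(df["x"].to_numpy(float)) | ~np.isfinite(df["y"].to_numpy(float))
    if bad.any():
        raise ValidationError(
            f"non-finite planar coordinates for lake {df.loc[bad, 'lake_id'].iloc[0]}"
        )


# ---------------------------------------------------------------------------
# filtering

@dataclass(frozen=True)
class FilterConfig:
    """Inclusion rules; defaults are the study's.

    Lake surface area strictly inside (``area_min``, ``area_max``) ha; sample
    date inside the summer window (inclusive on both endpoints); chlorophyll,
    TP and color all measured on the same (lake, date) record; maximum depth
    present.
    """

    area_min: float = 4.0
    area_max: float = 10_000.0
    season_start: tuple[int, int] = (6, 15)
    season_end: tuple[int, int] = (9, 15)
    require_triplet: bool = True
    require_depth: bool = True

    def __post_init__(self) -> None:
        if not self.area_min < self.area_max:
            raise ValueError("area_min must be below area_max")
        if self.season_start > self.season_end:
            raise ValueError("season window is empty")


#: Fixed order in which rules are applied (first failure attributed).
FILTER_RULES = ("area", "season", "triplet", "depth")


def apply_filters(df: pd.DataFrame, cfg: FilterConfig | None = None):
    """Apply inclusion rules; return (kept, drop_log).

    ``drop_log`` counts removals by the *first* failing rule in the fixed
    order area -> season -> triplet -> depth; the kept set itself is
    order-invariant.
    """
    cfg = cfg or FilterConfig()
    fails = {}
    area = df["lake_area"]
    fails["area"] = ~((area > cfg.area_min) & (area < cfg.area_max)) | area.isna()
    dates = pd.to_datetime(df["date"])
    monthday = list(zip(dates.dt.month, dates.dt.day))
    in_season = np.array(
        [cfg.season_start <= md <= cfg.season_end for md in monthday]
    )
    fails["season"] = ~in_season | dates.isna().to_numpy()
    if cfg.require_triplet:
        fails["triplet"] = df[["chl", "tp", "color"]].isna().any(axis=1).to_numpy()
    else:
        fails["triplet"] = np.zeros(len(df), dtype=bool)
    if cfg.require_depth:
        fails["depth"] = df["max_depth"].isna().to_numpy()
    else:
        fails["depth"] = np.zeros(len(df), dtype=bool)

    drop_log = {rule: 0 for rule in FILTER_RULES}
    dropped = np.zeros(len(df), dtype=bool)
    for rule in FILTER_RULES:
        hit = np.asarray(fails[rule]) & ~dropped
        drop_log[rule] = int(hit.sum())
        dropped |= hit
    kept = df.loc[~dropped].reset_index(drop=True)
    return kept, drop_log


# ---------------------------------------------------------------------------
# model frame

@dataclass
class ModelFrame:
    """Design matrices and site structure for one candidate model.

    ``y`` is log10 chlorophyll; ``X_svc`` the (n, 3) spatially-varying design
    [1, log10 TP, log10 color]; ``X_fixed`` the (n, p) space-invariant design
    (possibly p = 0).  ``sites`` lists each unique lake once (km coordinates);
    ``site_index[i]`` maps row i to its lake's position in ``sites``.
    ``lake_table`` carries one row of lake-level attributes per site for the
    post-hoc analyses.
    """

    y: np.ndarray
    X_svc: np.ndarray
    X_fixed: np.ndarray
    svc_names: tuple
    fixed_names: tuple
    sites: np.ndarray
    site_ids: np.ndarray
    site_index: np.ndarray
    lake_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n = len(self.y)
        if not (self.X_svc.shape[0] == n == self.X_fixed.shape[0] == len(self.site_index)):
            raise ValueError("row counts disagree across response and designs")
        if len(np.unique(self.site_index)) != len(self.sites):
            raise ValueError("every site must have at least one row")
        for name, arr in (("y", self.y), ("X_svc", self.X_svc), ("X_fixed", self.X_fixed)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset(self, rows: np.ndarray) -> "ModelFrame":
        """Frame restricted to the given row indices (sites re-derived)."""
        rows = np.asarray(rows)
        old_sites = self.site_index[rows]
        kept_sites, new_index = np.unique(old_sites, return_inverse=True)
        lake_table = None
        if self.lake_table is not None:
            lake_table = self.lake_table.iloc[kept_sites].reset_index(drop=True)
        return ModelFrame(
            y=self.y[rows],
            X_svc=self.X_svc[rows],
            X_fixed=self.X_fixed[rows],
            svc_names=self.svc_names,
            fixed_names=self.fixed_names,
            sites=self.sites[kept_sites],
            site_ids=self.site_ids[kept_sites],
            site_index=new_index,
            lake_table=lake_table,
        )


def _log10_column(values, name, lake_ids):
    values = np.asarray(values, dtype=float)
    bad = ~(values > 0) | ~np.isfinite(values)
    if bad.any():
        raise ValidationError(
            f"log10 of nonpositive {name} for lake {np.asarray(lake_ids)[bad][0]}"
        )
    return np.log10(values)


def build_model_frame(
    df: pd.DataFrame,
    fixed_terms=DEFAULT_FIXED_TERMS,
    jitter_km: float = 0.001,
    jitter_seed: int = 0,
) -> ModelFrame:
    """Assemble the model frame from filtered observations.

    log10 transforms chlorophyll (response), TP, color, maximum depth and the
    catchment-to-lake area ratio (CA:LK); the drainage dummy is 1 for drainage
    lakes, 0 for isolated.  ``fixed_terms`` selects any subset (possibly
    empty) of :data:`DEFAULT_FIXED_TERMS`.  Distinct lakes at identical
    coordinates are jittered by ``jitter_km`` (with a loud warning) so spatial
    covariance matrices stay nonsingular.
    """
    df = df.reset_index(drop=True)
    ids = df["lake_id"].to_numpy()
    y = _log10_column(df["chl"], "chl", ids)
    X_svc = np.column_stack([
        np.ones(len(df)),
        _log10_column(df["tp"], "tp", ids),
        _log10_column(df["color"], "color", ids),
    ])

    cols = {}
    if "log_max_depth" in fixed_terms:
        cols["log_max_depth"] = _log10_column(df["max_depth"], "max_depth", ids)
    if "log_calk" in fixed_terms:
        calk = df["catchment_area"].to_numpy(float) / df["lake_area"].to_numpy(float)
        cols["log_calk"] = _log10_column(calk, "catchment_area/lake_area", ids)
    for p in ("prop_agriculture", "prop_wetland", "prop_urban", "prop_forest"):
        if p in fixed_terms:
            cols[p] = df[p].to_numpy(float)
    if "drainage" in fixed_terms:
        cols["drainage"] = (df["connectivity"].astype(str) == "drainage").astype(float).to_numpy()
    unknown = set(fixed_terms) - set(cols)
    if unknown:
        raise ValueError(f"unknown fixed terms: {sorted(unknown)}")
    ordered = tuple(t for t in fixed_terms if t in cols)
    X_fixed = (
        np.column_stack([cols[t] for t in ordered])
        if ordered else np.empty((len(df), 0))
    )

    site_ids, site_index = np.unique(ids, return_inverse=True)
    first_row = np.zeros(len(site_ids), dtype=int)
    first_row[site_index[::-1]] = np.arange(len(df))[::-1]
    sites = df[["x", "y"]].to_numpy(float)[first_row]
    sites = _jitter_coincident(sites, site_ids, jitter_km, jitter_seed)

    lake_cols = [c for c in SCHEMA if c in df.columns and c not in ("date",)]
    lake_table = df.iloc[first_row][lake_cols].reset_index(drop=True)
    lake_table[["x", "y"]] = sites

    return ModelFrame(
        y=y, X_svc=X_svc, X_fixed=X_fixed,
        svc_names=SVC_TERMS, fixed_names=ordered,
        sites=sites, site_ids=site_ids, site_index=site_index,
        lake_table=lake_table,
    )


def _jitter_coincident(sites, site_ids, jitter_km, seed):
    if len(sites) < 2 or jitter_km <= 0:
        return sites
    sites = sites.copy()
    rng = np.random.default_rng(seed)
    for _ in range(100):
        _, first = np.unique(np.round(sites, 9), axis=0, return_index=True)
        dup = np.setdiff1d(np.arange(len(sites)), first)
        if dup.size == 0:
            return sites
        warnings.warn(
            f"jittering {dup.size} coincident lake coordinates by {jitter_km} km: "
            f"{list(np.asarray(site_ids)[dup][:5])}",
            stacklevel=3,
        )
        sites[dup] += rng.normal(scale=jitter_km, size=(dup.size, 2))
    raise ValidationError("could not separate coincident sites by jittering")


def split_holdout(frame: ModelFrame, fraction: float = 0.10, seed: int | None = None):
    """Random observation-level train/holdout split.

    Holdout size is floor(fraction * n); a multi-observation lake may appear
    in both partitions.  Reproducible under a fixed seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    n = frame.n_obs
    n_hold = int(np.floor(fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    hold_rows = np.sort(perm[:n_hold])
    train_rows = np.sort(perm[n_hold:])
    return frame.subset(train_rows), frame.subset(hold_rows)


def nearest_neighbor_summary(sites: np.ndarray):
    """(median, min, max) of each site's nearest-neighbour distance in km."""
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    if sites.shape[0] < 2:
        raise ValueError("need at least two sites")
    dist, _ = cKDTree(sites).query(sites, k=2)
    nn = dist[:, 1]
    return float(np.median(nn)), float(nn.min()), float(nn.max())
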