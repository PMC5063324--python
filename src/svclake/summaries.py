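"""Scientific summaries of the fitted coefficient fields.

Turns posterior site-level coefficients into the quantities a limnologist
reports: per-lake significance of TP and color effects (95% credible interval
excluding zero), natural-scale effect sizes (ug/L chlorophyll per unit
predictor), interpolated coefficient surfaces, Pearson correlations of the
coefficients with lake/catchment covariates, and Welch t-test contrasts
between connectivity classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def coefficient_field(results, prob: float = 0.95) -> pd.DataFrame:
    """Per-lake posterior summary of each spatially-varying coefficient.

    Columns per term: ``{term}_mean``, ``{term}_sd``, ``{term}_q2.5``,
    ``{term}_q97.5`` and ``{term}_sig`` in {"positive", "negative", "null"}.
    """
    post = results.posterior
    if post.site_coeffs is None:
        raise ValueError("coefficient fields require a spatial fit")
    alpha = (1.0 - prob) / 2.0
    frame = results.frame
    out = pd.DataFrame({
        "lake_id": frame.site_ids,
        "x": frame.sites[:, 0],
        "y": frame.sites[:, 1],
    })
    for j, term in enumerate(post.svc_names):
        draws = post.site_coeffs[:, :, j]
        lo = np.quantile(draws, alpha, axis=0)
        hi = np.quantile(draws, 1.0 - alpha, axis=0)
        out[f"{term}_mean"] = draws.mean(axis=0)
        out[f"{term}_sd"] = draws.std(axis=0, ddof=1)
        out[f"{term}_q2.5"] = lo
        out[f"{term}_q97.5"] = hi
        out[f"{term}_sig"] = np.where(lo > 0, "positive",
                                      np.where(hi < 0, "negative", "null"))
    return out


def classify_significance(field: pd.DataFrame, terms=None) -> dict:
    """Counts and class-wise summaries of significant lakes per term.

    A lake is positive when its 2.5% quantile exceeds 0, negative when its
    97.5% quantile is below 0, otherwise null (a boundary exactly at zero is
    not excluded).  Returns, per term, the class counts plus the mean and sd
    of the posterior-mean coefficients within each class.
    """
    if terms is None:
        terms = sorted({c[:-5] for c in field.columns if c.endswith("_mean")})
    out = {}
    for term in terms:
        cls = field[f"{term}_sig"]
        means = field[f"{term}_mean"]
        summary = {}
        for label in ("positive", "negative", "null"):
            sel = means[cls == label]
            summary[label] = {
                "n": int(sel.size),
                "mean": float(sel.mean()) if sel.size else np.nan,
                "sd": float(sel.std(ddof=1)) if sel.size > 1 else np.nan,
            }
        out[term] = summary
    return out


def translate_effect(slope, chl, ref_value):
    """Natural-scale effect: d CHL / d X of the power law CHL = c X^slope.

    With both variables log10-transformed, the slope is an elasticity, so the
    derivative at a reference point (chl, ref_value) is slope * chl /
    ref_value — e.g. ug/L chlorophyll per ug/L TP at that lake's typical
    values.  Linear in slope and chl, inverse in ref_value.
    """
    chl = np.asarray(chl, dtype=float)
    ref_value = np.asarray(ref_value, dtype=float)
    if np.any(chl <= 0) or np.any(ref_value <= 0):
        raise ValueError("chl and ref_value must be positive")
    out = np.asarray(slope, dtype=float) * chl / ref_value
    return out if out.shape else float(out)


@dataclass
class SurfaceGrid:
    """Regular interpolation grid for one coefficient surface.

    ``values[i, j]`` corresponds to (x=xs[j], y=ys[i]).
    """

    xs: np.ndarray
    ys: np.ndarray
    values: np.ndarray
    term: str

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.xs, self.ys)
        return pd.DataFrame({
            "x": xx.ravel(), "y": yy.ravel(), self.term: self.values.ravel()})


def interpolate_surface(field: pd.DataFrame, term: str, cell_km: float | None = None,
                        n_cells: int = 50, power: float = 2.0) -> SurfaceGrid:
    """Inverse-distance-weighted surface of posterior-mean coefficients.

    IDW with the given power (default 2) over the lake bounding box; a grid
    node coincident with a lake takes that lake's value exactly.  Surfaces are
    presentation artifacts, not inference.
    """
    if len(field) < 3:
        raise ValueError("need at least three lakes to interpolate")
    pts = field[["x", "y"]].to_numpy(float)
    vals = field[f"{term}_mean"].to_numpy(float)
    x0, x1 = pts[:, 0].min(), pts[:, 0].max()
    y0, y1 = pts[:, 1].min(), pts[:, 1].max()
    if x1 <= x0 or y1 <= y0:
        raise ValueError("degenerate grid: lakes span zero extent")
    if cell_km is not None:
        xs = np.arange(x0, x1 + cell_km, cell_km)
        ys = np.arange(y0, y1 + cell_km, cell_km)
    else:
        xs = np.linspace(x0, x1, n_cells)
        ys = np.linspace(y0, y1, n_cells)
    xx, yy = np.meshgrid(xs, ys)
    nodes = np.column_stack([xx.ravel(), yy.ravel()])
    d = np.sqrt(((nodes[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    out = np.empty(len(nodes))
    exact = d < 1e-12
    has_exact = exact.any(axis=1)
    out[has_exact] = vals[np.argmax(exact[has_exact], axis=1)]
    rest = ~has_exact
    wgt = 1.0 / d[rest] ** power
    out[rest] = (wgt * vals).sum(axis=1) / wgt.sum(axis=1)
    return SurfaceGrid(xs=xs, ys=ys, values=out.reshape(len(ys), len(xs)), term=term)


def correlate_with_covariates(field: pd.DataFrame, lake_table: pd.DataFrame,
                              covariates, terms=None, alpha: float = 0.05) -> pd.DataFrame:
    """Pearson r of per-lake coefficients against lake/catchment covariates.

    Tables are matched on ``lake_id``.  Returns a tidy frame with r, the
    two-sided p-value, and a significance flag at ``alpha``.  P-values are
    reported unadjusted for multiplicity.
    """
    if terms is None:
        terms = sorted({c[:-5] for c in field.columns if c.endswith("_mean")})
    merged = field.merge(lake_table, on="lake_id", suffixes=("", "_lake"))
    rows = []
    for term in terms:
        coeff = merged[f"{term}_mean"].to_numpy(float)
        for cov in covariates:
            vals = merged[cov].to_numpy(float)
            if np.std(vals) == 0:
                raise ValueError(f"covariate {cov!r} has zero variance")
            r, p = stats.pearsonr(coeff, vals)
            rows.append({"term": term, "covariate": cov, "r": r, "p": p,
                         "significant": bool(p < alpha)})
    return pd.DataFrame(rows)


def contrast_by_connectivity(field: pd.DataFrame, connectivity, terms=None) -> pd.DataFrame:
    """Welch two-sample t-tests of coefficient means between lake types.

    Compares drainage vs isolated lakes per term with the unequal-variance t
    statistic and Welch-Satterthwaite degrees of freedom.
    """
    if terms is None:
        terms = sorted({c[:-5] for c in field.columns if c.endswith("_mean")})
    connectivity = np.asarray(connectivity).astype(str)
    rows = []
    for term in terms:
        vals = field[f"{term}_mean"].to_numpy(float)
        a = vals[connectivity == "drainage"]
        b = vals[connectivity == "isolated"]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each connectivity group needs at least two lakes")
        res = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"term": term, "t": float(res.statistic),
                     "df": float(res.df), "p": float(res.pvalue)})
    return pd.DataFrame(rows)


def plot_surface(grid: SurfaceGrid, field: pd.DataFrame | None = None, ax=None):
    """Render an interpolated coefficient surface (matplotlib, optional)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.pcolormesh(grid.xs, grid.ys, grid.values, cmap="coolwarm",
                       shading="auto")
    if field is not None:
        ax.scatter(field["x"], field["y"], s=6, c="k", alpha=0.5)
    ax.set_xlabel("x (km)")
    ax.set_ylabel("y (km)")
    ax.set_title(grid.term)
    plt.colorbar(im, ax=ax, label=grid.term)
    return ax
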