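"""Daily abundance prediction on a nearshore grid, with ExDet filtering.

Predictions are made on a 5 km grid clipped to the band between the
coastline and 5 km from shore, daily from 15 May to 30 August.  Each
cell-day abundance is area x exp(linear predictor); days containing any
cell whose ExDet extrapolation score falls outside [-0.15, 1.15] for the
dynamic covariates (SST, cumulative CUTI, cumulative relaxation) are
excluded before summarising, because predictions into environmental
conditions never sampled during surveys are unreliable.

ExDet follows the univariate/combinatorial decomposition: NT1 sums, over
covariates, the scaled shortfall below the reference minimum or excess
above the maximum (<= 0, 0 inside all ranges); for points inside all
univariate ranges, NT2 is the squared Mahalanobis distance to the
reference mean scaled by the largest reference Mahalanobis distance, so
values > 1 flag novel covariate combinations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon, box

from . import covariates as cov
from ._geo import Coastline

DYNAMIC_COVARIATES = ("sst", "cum_cuti", "cum_relax")


# ---------------------------------------------------------------------------
# prediction grid


def _nearshore_band(coastline: Coastline, max_offshore: float) -> Polygon:
    pts = list(zip(coastline.shore_x, coastline.y))
    line = LineString(pts)
    xmin = float(coastline.shore_x.min() - max_offshore - 10.0)
    ocean = Polygon(
        pts
        + [
            (xmin, coastline.y[-1]),
            (xmin, coastline.y[0]),
        ]
    )
    band = ocean.intersection(line.buffer(max_offshore))
    return band


def make_grid(
    coastline: Coastline,
    cell: float = 5.0,
    max_offshore: float = 5.0,
    region_breaks: tuple = None,
) -> pd.DataFrame:
    """Prediction cells clipped to the nearshore band.

    Returns one row per cell with its clipped area (km^2), clipped-polygon
    centroid, and region (from ``region_breaks`` alongshore boundaries,
    south to north; all 1 when omitted).
    """
    band = _nearshore_band(coastline, max_offshore)
    x_lo = float(coastline.shore_x.min() - max_offshore - cell)
    x_hi = float(coastline.shore_x.max() + cell)
    y0, y1 = float(coastline.y[0]), float(coastline.y[-1])
    rows = []
    cid = 0
    for yb in np.arange(y0, y1, cell):
        for xb in np.arange(x_lo, x_hi, cell):
            poly = box(xb, yb, xb + cell, yb + cell).intersection(band)
            if poly.is_empty or poly.area < 1e-9:
                continue
            c = poly.centroid
            rows.append(
                dict(
                    cell_id=f"C{cid:04d}",
                    x=float(c.x),
                    y=float(c.y),
                    area_km2=float(poly.area),
                )
            )
            cid += 1
    grid = pd.DataFrame(rows)
    grid["lat"] = coastline.lat_of(grid["y"].to_numpy())
    if region_breaks is not None:
        y23, y12 = region_breaks
        grid["region"] = np.where(
            grid["y"] >= y12, 1, np.where(grid["y"] >= y23, 2, 3)
        )
    else:
        grid["region"] = 1
    return grid


def grid_covariates(
    grid: pd.DataFrame,
    layers: cov.StaticLayers,
    dynamic: pd.DataFrame,
    sst: pd.DataFrame,
    dates,
    include_dist_cape: bool = True,
) -> pd.DataFrame:
    """Long per-cell-per-day covariate table for prediction.

    Static layers are extracted once at cell centroids; cumulative CUTI /
    relaxation join on (date, 1-degree latitude bin) and SST by nearest
    grid latitude and exact date.
    """
    g = grid.copy()
    x = g["x"].to_numpy()
    y = g["y"].to_numpy()
    shore = layers.coastline.shore_at(y)
    g["depth"] = cov.sample_ocean(layers.depth, x, y, shore)
    g["dist_coast"] = shore - x
    g["shelf_width"] = cov.shelf_width_at(layers.shelf_table, y)
    if include_dist_cape and layers.capes:
        g["dist_cape"] = cov.dist_cape(x, y, layers.capes)
    g["dist_estuary"] = cov.dist_estuary(x, y, layers.coastline.estuaries)
    g["substrate"] = [
        cov.substrate_of_segment(xi, yi, 5.0, layers.substrate) or "soft"
        for xi, yi in zip(x, y)
    ]
    g["lat_bin"] = np.floor(g["lat"]) + 0.5

    dates = pd.to_datetime(pd.Index(dates))
    long = g.merge(pd.DataFrame({"date": dates}), how="cross")
    dyn = dynamic.copy()
    dyn["date"] = pd.to_datetime(dyn["date"])
    long = long.merge(
        dyn[["date", "lat_bin", "cum_cuti", "cum_relax"]],
        on=["date", "lat_bin"],
        how="left",
    )
    sst = sst.copy()
    sst["date"] = pd.to_datetime(sst["date"])
    sst_lats = np.sort(sst["lat"].unique())
    long["sst_lat"] = sst_lats[
        np.argmin(
            np.abs(long["lat"].to_numpy()[:, None] - sst_lats[None, :]), axis=1
        )
    ]
    long = long.merge(
        sst.rename(columns={"lat": "sst_lat"})[["date", "sst_lat", "sst"]],
        on=["date", "sst_lat"],
        how="left",
    ).drop(columns=["sst_lat"])
    return long


def prediction_dates(year: int) -> pd.DatetimeIndex:
    """The daily prediction window, 15 May through 30 August."""
    return pd.date_range(f"{year}-05-15", f"{year}-08-30", freq="D")


# ---------------------------------------------------------------------------
# daily prediction


def predict_daily(fit, grid_cov: pd.DataFrame) -> pd.DataFrame:
    """Per-cell whales per day: N = area x exp(linear predictor).

    Cells with any missing covariate are masked (dropped) for that day.
    """
    needed = (
        list(fit.config.smooth_terms)
        + (list(fit.config.interaction) if fit.config.interaction else [])
        + list(fit.config.parametric_terms)
    )
    gc = grid_cov.dropna(subset=[c for c in needed if c in grid_cov.columns])
    gc = gc.reset_index(drop=True)
    offset = np.log(gc["area_km2"].to_numpy(dtype=float))
    eta = fit.predict(gc, offset=offset)
    out = gc[["cell_id", "date", "region", "area_km2"]].copy()
    out["N_hat"] = np.exp(eta)
    return out


# ---------------------------------------------------------------------------
# extrapolation detection


def exdet(reference: pd.DataFrame, target: pd.DataFrame,
          covariates=DYNAMIC_COVARIATES) -> np.ndarray:
    """ExDet extrapolation score per target row.

    NT1 (univariate): sum over covariates of
    min(0, (x - min)/(max - min), (max - x)/(max - min)); negative outside
    any reference range.  NT2 (combinatorial, for NT1 = 0 rows): squared
    Mahalanobis distance to the reference mean divided by the maximum over
    the reference points.  Returns NT1 where NT1 < 0, else NT2.
    """
    covariates = [c for c in covariates if c in reference.columns]
    R = reference[covariates].to_numpy(dtype=float)
    T = target[list(covariates)].to_numpy(dtype=float)
    lo = R.min(axis=0)
    hi = R.max(axis=0)
    rng = np.where(hi > lo, hi - lo, 1.0)
    a = (T - lo) / rng
    b = (hi - T) / rng
    nt1 = np.minimum(0.0, np.minimum(a, b)).sum(axis=1)

    mu = R.mean(axis=0)
    C = np.cov(R, rowvar=False)
    C = np.atleast_2d(C)
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError:
        warnings.warn("singular reference covariance; using pseudo-inverse",
                      stacklevel=2)
        Cinv = np.linalg.pinv(C)
    def maha(M):
        d = M - mu
        return np.einsum("ij,jk,ik->i", d, Cinv, d)

    m_ref_max = maha(R).max()
    nt2 = maha(T) / m_ref_max
    return np.where(nt1 < 0, nt1, nt2)


def filter_extrapolated_days(
    predictions: pd.DataFrame,
    exdet_values: np.ndarray,
    lo: float = -0.15,
    hi: float = 1.15,
    log: list | None = None,
) -> pd.DataFrame:
    """Flag whole days whose grid contains any extrapolated cell.

    A (region, date) is excluded when any of its cells has ExDet > ``hi``
    or < ``lo``; the returned frame adds ``exdet`` and ``included``.
    """
    pred = predictions.copy()
    pred["exdet"] = np.asarray(exdet_values, dtype=float)
    bad = (pred["exdet"] > hi) | (pred["exdet"] < lo)
    bad_days = pred.loc[bad, ["region", "date"]].drop_duplicates()
    bad_keys = set(map(tuple, bad_days.to_numpy()))
    pred["included"] = [
        (r, d) not in bad_keys for r, d in zip(pred["region"], pred["date"])
    ]
    if log is not None:
        for r, d in sorted(bad_keys, key=str):
            log.append(f"region {r} {pd.Timestamp(d).date()}: excluded (ExDet)")
    return pred


# ---------------------------------------------------------------------------
# summaries


def daily_abundance(predictions: pd.DataFrame) -> pd.DataFrame:
    """Regional daily abundance: sum of cell abundances (exact conservation)."""
    out = (
        predictions.groupby(["region", "date"], as_index=False)
        .agg(N_hat=("N_hat", "sum"), included=("included", "all"))
    )
    return out


def annual_summary(
    fit,
    predictions: pd.DataFrame,
    grid_cov: pd.DataFrame,
    B: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-year mean daily abundance and uncertainty, per region.

    The point estimate is the mean of regional daily abundance over
    ExDet-included days.  ``sd_boot`` and the percentile interval
    ``(N_lo, N_hi)`` come from a parametric bootstrap over the coefficient
    posterior (B redraws, re-predicting every included cell-day); the
    percentile interval respects the right skew of exp-scale abundance.
    ``sd_within`` is the within-season spread of the daily series (sd
    across included days).  Years with no included days are reported with
    NaN and a warning.
    """
    daily = daily_abundance(predictions)
    daily["year"] = pd.to_datetime(daily["date"]).dt.year
    inc = daily[daily["included"]]
    point = inc.groupby(["region", "year"], as_index=False).agg(
        N_mean=("N_hat", "mean"),
        n_days=("N_hat", "size"),
        sd_within=("N_hat", "std"),
    )
    all_years = daily[["region", "year"]].drop_duplicates()
    point = all_years.merge(point, on=["region", "year"], how="left")
    empty = point[point["n_days"].isna()]
    for _, row in empty.iterrows():
        warnings.warn(
            f"region {row['region']} year {row['year']}: no included days",
            stacklevel=2,
        )

    # bootstrap: re-predict included cell-days under coefficient redraws
    keep_keys = set(
        map(tuple, inc[["region", "date"]].to_numpy())
    )
    needed = (
        list(fit.config.smooth_terms)
        + (list(fit.config.interaction) if fit.config.interaction else [])
        + list(fit.config.parametric_terms)
    )
    gc = grid_cov.dropna(subset=[c for c in needed if c in grid_cov.columns])
    gc = gc.reset_index(drop=True)
    mask = [
        (r, d) in keep_keys for r, d in zip(gc["region"], gc["date"])
    ]
    gc = gc[mask].reset_index(drop=True)
    if len(gc) == 0 or B <= 0:
        point["sd_boot"] = np.nan
        point["N_lo"] = np.nan
        point["N_hi"] = np.nan
        return point
    X = fit._model_matrix(gc)
    offset = np.log(gc["area_km2"].to_numpy(dtype=float))
    rng = np.random.default_rng(seed)
    betas = fit.sample_coefficients(B, rng)
    eta = np.clip(X @ betas.T + offset[:, None], -30, 30)  # (rows, B)
    N = np.exp(eta)
    gc = gc.copy()
    gc["year"] = pd.to_datetime(gc["date"]).dt.year
    groups = gc.groupby(["region", "year", "date"]).indices
    frame = []
    for (r, yr, d), idx in groups.items():
        frame.append((r, yr, d, N[idx].sum(axis=0)))
    by_day = pd.DataFrame(
        [(r, yr, d) for r, yr, d, _ in frame], columns=["region", "year", "date"]
    )
    mat = np.vstack([v for *_, v in frame])  # (days, B)
    sd_rows = []
    for (r, yr), idx in by_day.groupby(["region", "year"]).indices.items():
        annual_draws = mat[idx].mean(axis=0)
        sd_rows.append(
            (
                r, yr,
                float(annual_draws.std(ddof=1)),
                float(np.quantile(annual_draws, 0.025)),
                float(np.quantile(annual_draws, 0.975)),
            )
        )
    sd_df = pd.DataFrame(
        sd_rows, columns=["region", "year", "sd_boot", "N_lo", "N_hi"]
    )
    return point.merge(sd_df, on=["region", "year"], how="left")


def hotspot_maps(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-cell long-term mean abundance and coefficient of variation.

    Means and CV (sd/mean) are taken across ExDet-included days; cells
    whose mean is zero have undefined CV (NaN).
    """
    inc = predictions[predictions["included"]]
    out = inc.groupby("cell_id", as_index=False).agg(
        mean_N=("N_hat", "mean"), sd_N=("N_hat", "std"), n_days=("N_hat", "size")
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out["cv"] = np.where(out["mean_N"] > 0, out["sd_N"] / out["mean_N"], np.nan)
    return out
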