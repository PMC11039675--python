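"""Habitat covariates for nearshore density surface models.

Derives the environmental covariates used to model gray whale density:

* five static layers — depth, distance to coast, shelf width (distance to
  the 200 m isobath, one value per latitude), signed distance to the
  nearest prominent cape, distance to the nearest large river estuary —
  plus a hard/soft benthic substrate classification per segment;
* sea-surface temperature matched to segment centroids by nearest grid
  latitude and exact date;
* two upwelling-phenology indices built from the daily Coastal Upwelling
  Transport Index (CUTI): cumulative smoothed CUTI since the spring
  transition, and the cumulative count of relaxation-event days (days when
  smoothed CUTI falls below the climatological upwelling-season mean for
  the latitude bin).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._geo import Coastline, Raster

# ---------------------------------------------------------------------------
# static layers


def sample_ocean(raster: Raster, x, y, shore_x) -> np.ndarray:
    """Raster values at points, stepping offshore when the nearest cell is land.

    Points in the water (x < shore) whose nearest cell centre falls on land
    (NaN) are re-sampled up to two cells farther offshore; this mirrors the
    field practice of taking the closest wet grid value for very nearshore
    locations.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float)).copy()
    y = np.atleast_1d(np.asarray(y, dtype=float))
    shore_x = np.atleast_1d(np.asarray(shore_x, dtype=float))
    out = raster.sample(x, y)
    for _ in range(2):
        redo = np.isnan(out) & (x < shore_x)
        if not redo.any():
            break
        x[redo] -= raster.cell
        out[redo] = raster.sample(x[redo], y[redo])
    return out


def shelf_width(depth: Raster, coastline: Coastline) -> pd.DataFrame:
    """Distance (km) from the coast to the 200 m isobath, per raster row.

    A single value per latitude, applied across longitudes.  Rows where the
    200 m isobath is never reached (or that are all land) get NaN and are
    flagged in the ``missing`` column.
    """
    rows = []
    for i, y in enumerate(depth.y_coords):
        shore = coastline.shore_at(y)
        xs = depth.x_coords
        offshore = xs < shore
        d = depth.values[i]
        deep = offshore & np.isfinite(d) & (d >= 200.0)
        if not deep.any():
            rows.append((y, coastline.lat_of(y), np.nan, True))
            continue
        # first crossing moving offshore (decreasing x)
        x_iso = xs[deep].max()
        rows.append((y, coastline.lat_of(y), shore - x_iso, False))
    return pd.DataFrame(rows, columns=["y", "lat", "shelf_width_km", "missing"])


def shelf_width_at(table: pd.DataFrame, y) -> np.ndarray:
    """Interpolate a shelf-width table at alongshore coordinate(s) y."""
    ok = table[~table["missing"]]
    if ok.empty:
        raise ValueError("shelf width undefined everywhere (no 200 m isobath)")
    return np.interp(np.asarray(y, dtype=float), ok["y"].values,
                     ok["shelf_width_km"].values)


@dataclass
class Cape:
    x: float
    y: float
    lat: float
    deviation_km: float


def detect_capes(
    coastline: Coastline, smooth_window: float = 200.0, threshold: float = 5.0
) -> list[Cape]:
    """Locate prominent capes on a coastline.

    The coastline is smoothed with a centred moving average of its
    coordinates over ``smooth_window`` km of along-shore arc length
    (shrinking at the ends); contiguous runs where the high-resolution line
    deviates from the smoothed line by more than ``threshold`` km collapse
    to a single cape at the point of maximal deviation.
    """
    s = coastline.arc_length()
    if s[-1] < smooth_window:
        raise ValueError(
            f"coastline ({s[-1]:.0f} km) shorter than smoothing window"
        )
    xs, ys = coastline.shore_x, coastline.y
    # moving average over arc length; near the ends the window shrinks
    # symmetrically so the smoothed line is not dragged toward the interior
    half = np.minimum(smooth_window / 2.0, np.minimum(s - s[0], s[-1] - s))
    sm_x = np.empty_like(xs)
    sm_y = np.empty_like(ys)
    lo = np.searchsorted(s, s - half, side="left")
    hi = np.searchsorted(s, s + half, side="right")
    for i in range(len(s)):
        sl = slice(lo[i], hi[i])
        if hi[i] - lo[i] > 1:
            w = s[sl]
            sm_x[i] = np.trapezoid(xs[sl], w) / (w[-1] - w[0])
            sm_y[i] = np.trapezoid(ys[sl], w) / (w[-1] - w[0])
        else:
            sm_x[i], sm_y[i] = xs[i], ys[i]
    dev = np.hypot(xs - sm_x, ys - sm_y)
    above = dev > threshold
    capes: list[Cape] = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            k = i + int(np.argmax(dev[i : j + 1]))
            capes.append(
                Cape(
                    x=float(xs[k]),
                    y=float(ys[k]),
                    lat=float(coastline.lat_of(ys[k])),
                    deviation_km=float(dev[k]),
                )
            )
            i = j + 1
        else:
            i += 1
    return capes


def dist_cape(x, y, capes: Sequence[Cape]) -> np.ndarray:
    """Signed distance (km) to the nearest cape.

    Negative for points north of the nearest cape, positive for points
    south of it.  Equidistant points take the lower-index cape.
    """
    if len(capes) == 0:
        raise ValueError("no capes: distance-to-cape layer undefined")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    cx = np.array([c.x for c in capes])
    cy = np.array([c.y for c in capes])
    d = np.hypot(x[:, None] - cx[None, :], y[:, None] - cy[None, :])
    nearest = np.argmin(d, axis=1)  # argmin takes the first (lowest index) tie
    dist = d[np.arange(len(x)), nearest]
    north = y > cy[nearest]
    return np.where(north, -dist, dist)


def dist_estuary(x, y, estuaries: Sequence[dict], min_area_ha: float = 300.0):
    """Distance (km) to the nearest river estuary larger than ``min_area_ha``."""
    kept = [e for e in estuaries if e["area_ha"] > min_area_ha]
    if not kept:
        raise ValueError(
            f"no estuaries larger than {min_area_ha} ha; layer undefined"
        )
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    ex = np.array([e["x"] for e in kept])
    ey = np.array([e["y"] for e in kept])
    d = np.hypot(x[:, None] - ex[None, :], y[:, None] - ey[None, :])
    return d.min(axis=1)


def substrate_of_segment(
    cx: float, cy: float, length_km: float, substrate: Raster,
    bearing_deg: float = 0.0,
) -> str | None:
    """Predominant substrate class over a segment footprint.

    The substrate raster codes hard = 1, soft = 0.  The footprint is the
    set of raster cells crossed by the segment line (centroid, length and
    bearing, 0 deg = due north); majority vote, exact tie -> soft (the
    regionally dominant class).  Returns None when no cells are hit.
    """
    n = max(int(np.ceil(length_km / (substrate.cell / 4.0))) + 1, 2)
    t = np.linspace(-length_km / 2.0, length_km / 2.0, n)
    b = np.deg2rad(bearing_deg)
    px = cx + t * np.sin(b)
    py = cy + t * np.cos(b)
    i, j = substrate.index_of(px, py)
    ok = (i >= 0) & (i < substrate.ny) & (j >= 0) & (j < substrate.nx)
    if not ok.any():
        return None
    cells = {(ii, jj) for ii, jj in zip(i[ok], j[ok])}
    vals = np.array([substrate.values[c] for c in cells])
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return None
    n_hard = int((vals == 1).sum())
    n_soft = int((vals == 0).sum())
    return "hard" if n_hard > n_soft else "soft"


# ---------------------------------------------------------------------------
# upwelling phenology


def smooth_cuti(cuti: pd.DataFrame, window: int = 10) -> pd.DataFrame:
    """Centred moving average of daily CUTI per latitude bin.

    Edges use window shrinkage.  The series must be contiguous daily within
    each ``lat_bin``; gaps raise with the missing dates listed.

    Note the even default window means the centred average spans one more
    day before than after the target day, so a pure linear ramp is shifted
    by half a day's increment; this is the cost of matching the stated
    10-day filter length exactly.
    """
    out = cuti.copy()
    out["date"] = pd.to_datetime(out["date"])
    out = out.sort_values(["lat_bin", "date"]).reset_index(drop=True)
    smoothed = []
    for lat_bin, grp in out.groupby("lat_bin", sort=False):
        dates = grp["date"]
        full = pd.date_range(dates.iloc[0], dates.iloc[-1], freq="D")
        missing = full.difference(pd.DatetimeIndex(dates))
        if len(missing) > 0:
            raise ValueError(
                f"CUTI series for lat_bin {lat_bin} has gaps: "
                f"{[str(d.date()) for d in missing[:10]]}"
            )
        sm = grp["cuti"].rolling(window, center=True, min_periods=1).mean()
        smoothed.append(sm)
    out["cuti_smoothed"] = pd.concat(smoothed).sort_index()
    return out


@dataclass
class UpwellingPhenology:
    """Spring transition and season end for one year and latitude bin.

    Dates follow the cumulative-upwelling definition: the spring transition
    is the date of the minimum of the within-year running cumulative sum of
    smoothed CUTI, and the season end the date of its maximum.
    """

    year: int
    lat_bin: float
    spring_transition: pd.Timestamp
    season_end: pd.Timestamp
    degenerate: bool = False


def upwelling_phenology(
    smoothed: pd.DataFrame, year: int, lat_bin: float
) -> UpwellingPhenology:
    """Phenological dates from one year of a smoothed CUTI series."""
    grp = smoothed[
        (pd.to_datetime(smoothed["date"]).dt.year == year)
        & (smoothed["lat_bin"] == lat_bin)
    ].sort_values("date")
    if grp.empty:
        raise ValueError(f"no CUTI data for year {year}, lat_bin {lat_bin}")
    dates = pd.to_datetime(grp["date"]).to_numpy()
    csum = np.cumsum(grp["cuti_smoothed"].to_numpy())
    i_min = int(np.argmin(csum))
    i_max = int(np.argmax(csum))
    degenerate = not (i_min < i_max) or i_min == 0 or i_max == len(csum) - 1
    if i_min >= i_max:  # all-negative or all-positive year: pin the boundary
        i_min, i_max = 0, len(csum) - 1
    return UpwellingPhenology(
        year=year,
        lat_bin=lat_bin,
        spring_transition=pd.Timestamp(dates[i_min]),
        season_end=pd.Timestamp(dates[i_max]),
        degenerate=degenerate,
    )


def cumulative_cuti(
    smoothed: pd.DataFrame, phenology: UpwellingPhenology
) -> pd.Series:
    """Running sum of smoothed CUTI since the spring transition.

    Zero on and before the transition date (the cumulative index restarts
    there); indexed by date for the phenology's year and latitude bin.
    """
    grp = smoothed[
        (pd.to_datetime(smoothed["date"]).dt.year == phenology.year)
        & (smoothed["lat_bin"] == phenology.lat_bin)
    ].sort_values("date")
    dates = pd.to_datetime(grp["date"])
    vals = grp["cuti_smoothed"].to_numpy()
    after = (dates > phenology.spring_transition).to_numpy()
    out = np.cumsum(np.where(after, vals, 0.0))
    out[~after] = 0.0
    return pd.Series(out, index=dates.values, name="cum_cuti")


def relaxation_threshold(
    smoothed: pd.DataFrame,
    phenologies: Sequence[UpwellingPhenology],
    lat_bin: float,
) -> float:
    """Climatological relaxation threshold for one latitude bin.

    Mean of smoothed CUTI over all upwelling-season days (spring transition
    through season end), pooled across every study year.
    """
    phen = [p for p in phenologies if p.lat_bin == lat_bin]
    if not phen:
        raise ValueError(f"no phenology for lat_bin {lat_bin}")
    sub = smoothed[smoothed["lat_bin"] == lat_bin].copy()
    dates = pd.to_datetime(sub["date"])
    pool = []
    for p in phen:
        in_season = (dates > p.spring_transition) & (dates <= p.season_end)
        pool.append(sub.loc[in_season.values, "cuti_smoothed"].to_numpy())
    pooled = np.concatenate(pool)
    if pooled.size == 0:
        raise ValueError("no in-season days to average")
    return float(pooled.mean())


def cumulative_relaxation(
    smoothed: pd.DataFrame,
    threshold: float,
    phenology: UpwellingPhenology,
) -> pd.Series:
    """Cumulative count of relaxation-event days since the spring transition.

    A relaxation day is one whose smoothed CUTI is strictly below the
    climatological threshold; boundary equality is not an event.
    """
    grp = smoothed[
        (pd.to_datetime(smoothed["date"]).dt.year == phenology.year)
        & (smoothed["lat_bin"] == phenology.lat_bin)
    ].sort_values("date")
    dates = pd.to_datetime(grp["date"])
    relax = (grp["cuti_smoothed"].to_numpy() < threshold).astype(float)
    after = (dates > phenology.spring_transition).to_numpy()
    out = np.cumsum(np.where(after, relax, 0.0))
    out[~after] = 0.0
    return pd.Series(out, index=dates.values, name="cum_relax")


def build_dynamic_series(
    cuti: pd.DataFrame, years: Sequence[int] | None = None, window: int = 10
) -> pd.DataFrame:
    """Full dynamic-covariate table from a raw daily CUTI table.

    Smooths, derives per-year phenology, pools the relaxation threshold
    across all years per latitude bin, and returns one row per
    (date, lat_bin) with ``cum_cuti`` and ``cum_relax``.
    """
    sm = smooth_cuti(cuti, window=window)
    sm_years = pd.to_datetime(sm["date"]).dt.year
    if years is None:
        years = sorted(sm_years.unique())
    frames = []
    for lat_bin in sorted(sm["lat_bin"].unique()):
        phens = [upwelling_phenology(sm, y, lat_bin) for y in years]
        thr = relaxation_threshold(sm, phens, lat_bin)
        for p in phens:
            cc = cumulative_cuti(sm, p)
            cr = cumulative_relaxation(sm, thr, p)
            frames.append(
                pd.DataFrame(
                    {
                        "date": cc.index,
                        "lat_bin": lat_bin,
                        "cum_cuti": cc.to_numpy(),
                        "cum_relax": cr.to_numpy(),
                        "spring_transition": p.spring_transition,
                        "relaxation_threshold": thr,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# assembly


@dataclass
class StaticLayers:
    """The static geospatial layers feeding the density surface model."""

    depth: Raster
    substrate: Raster
    coastline: Coastline
    shelf_table: pd.DataFrame = None
    capes: list = field(default_factory=list)

    @classmethod
    def build(cls, depth: Raster, substrate: Raster, coastline: Coastline,
              smooth_window: float = 200.0, cape_threshold: float = 5.0):
        table = shelf_width(depth, coastline)
        try:
            capes = detect_capes(coastline, smooth_window, cape_threshold)
        except ValueError:
            capes = []
        return cls(depth=depth, substrate=substrate, coastline=coastline,
                   shelf_table=table, capes=capes)


def extract_at_segments(
    layers: StaticLayers,
    dynamic: pd.DataFrame,
    sst: pd.DataFrame,
    segments: pd.DataFrame,
    include_dist_cape: bool = True,
    log: list | None = None,
) -> pd.DataFrame:
    """Attach all habitat covariates to survey segments.

    Static layers and SST are evaluated at segment centroids (``x``, ``y``
    planar km columns, or derived from lat); cumulative CUTI and relaxation
    are joined on (date, 1-degree latitude bin).  SST is matched by nearest
    grid latitude and exact date.  Segments whose centroid falls outside
    the depth raster are dropped and logged.
    """
    seg = segments.copy()
    seg["date"] = pd.to_datetime(seg["date"])
    if "x" not in seg.columns or "y" not in seg.columns:
        raise ValueError("segments need planar x/y centroid columns")
    inside = layers.depth.contains(seg["x"].to_numpy(), seg["y"].to_numpy())
    if log is not None:
        for sid in seg.loc[~inside, "segment_id"]:
            log.append(f"segment {sid}: centroid outside raster, dropped")
    seg = seg[inside].reset_index(drop=True)
    x = seg["x"].to_numpy()
    y = seg["y"].to_numpy()

    shore = layers.coastline.shore_at(y)
    seg["depth"] = sample_ocean(layers.depth, x, y, shore)
    seg["dist_coast"] = shore - x
    seg["shelf_width"] = shelf_width_at(layers.shelf_table, y)
    if include_dist_cape and layers.capes:
        seg["dist_cape"] = dist_cape(x, y, layers.capes)
    sub = []
    for _, row in seg.iterrows():
        bearing = row.get("bearing_deg", 0.0) if hasattr(row, "get") else 0.0
        sub.append(
            substrate_of_segment(
                row["x"], row["y"], row["length_km"], layers.substrate,
                bearing_deg=bearing if pd.notna(bearing) else 0.0,
            )
        )
    seg["substrate"] = sub
    seg["dist_estuary"] = dist_estuary(x, y, layers.coastline.estuaries)

    lat = layers.coastline.lat_of(y)
    seg["lat_bin"] = np.floor(lat) + 0.5

    dyn = dynamic.copy()
    dyn["date"] = pd.to_datetime(dyn["date"])
    seg = seg.merge(
        dyn[["date", "lat_bin", "cum_cuti", "cum_relax"]],
        on=["date", "lat_bin"],
        how="left",
    )

    sst = sst.copy()
    sst["date"] = pd.to_datetime(sst["date"])
    sst_lats = np.sort(sst["lat"].unique())
    nearest = sst_lats[
        np.argmin(np.abs(lat[:, None] - sst_lats[None, :]), axis=1)
    ]
    seg["sst_lat"] = nearest
    seg = seg.merge(
        sst.rename(columns={"lat": "sst_lat"})[["date", "sst_lat", "sst"]],
        on=["date", "sst_lat"],
        how="left",
    ).drop(columns=["sst_lat"])
    return seg
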