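"""Synthetic nearshore survey generator with known ground truth.

Builds every input the pipeline consumes — coastline and estuaries,
bathymetry and substrate rasters, daily CUTI and SST series, and simulated
line-transect surveys — from a :class:`TruthBundle` of known parameters, so
that detection, density-surface and abundance estimates can be checked
against the values that generated the data.

The survey layout mirrors the field design: contiguous 20 km primary
sampling units (PSUs) along the coast, each with four 5 km inshore segments
at random distances < 1500 m from shore and one diagonal offshore segment of
variable length reaching the offshore survey limit (5 km north of the
mid-coast break, 3 km south of it).  Whale groups are placed in each
segment's truncation-free strip with an over-dispersed (negative binomial)
count whose mean is density x 2w x length; each group receives a uniform
perpendicular distance and is detected with half-normal probability at the
segment's Beaufort sea state.  Beaufort 4 is rare (0.68% of segments), and a
fraction of sightings lack a recorded distance, as in the field data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import covariates as cov
from ._geo import KM_PER_DEG, Coastline, Raster

# ---------------------------------------------------------------------------
# design and truth


@dataclass
class SurveyDesign:
    """Geometry of the line-transect sampling scheme."""

    psu_length: float = 20.0        # km of coast per primary sampling unit
    inshore_segment_length: float = 5.0   # km
    inshore_max_dist: float = 1500.0      # m from shore
    offshore_limit_north: float = 5.0     # km, north of the mid-coast break
    offshore_limit_south: float = 3.0     # km
    n_inshore_per_psu: int = 4
    offshore_length_range: tuple = (3.0, 6.0)  # km, diagonal segment length

    def __post_init__(self):
        if self.n_inshore_per_psu < 1:
            raise ValueError("need at least one inshore segment per PSU")
        if self.inshore_max_dist >= 1000.0 * min(
            self.offshore_limit_north, self.offshore_limit_south
        ):
            raise ValueError("inshore band must lie inside the offshore limit")


#: Beaufort sea-state frequencies; BSS 4 at the observed 0.68% rarity.
BSS_PROBS = {0: 0.15, 1: 0.30, 2: 0.30, 3: 0.2432, 4: 0.0068}

#: Half-normal detection scale (m) per BSS level, worsening with sea state.
SIGMA_BY_BSS = {0: 450.0, 1: 400.0, 2: 350.0, 3: 290.0, 4: 240.0}

SIGHTABILITY_PROBS = {"poor": 0.1, "fair": 0.3, "good": 0.4, "excellent": 0.2}


def _default_density_response() -> dict:
    """Known covariate -> log-density responses driving the truth surface.

    Densities peak nearshore over wide shelves in warm water, on hard
    substrate, and under the optimal upwelling-relaxation combination:
    cumulative upwelling raises density only when accompanied by relaxation
    days.  Depth has no effect (a pure-noise covariate for shrinkage
    checks).
    """
    return {
        "intercept": -2.0,
        "dist_coast": lambda d: -0.45 * d,
        "shelf_width": lambda s: 0.05 * (s - 15.0),
        "sst": lambda t: 0.15 * (t - 12.0),
        "depth": lambda z: 0.0 * z,
        "dist_estuary": lambda d: -0.015 * d,
        "substrate": {"hard": 0.4, "soft": 0.0},
        ("cum_cuti", "cum_relax"): lambda cc, cr: (
            2.2 * (cc / 150.0) * (cr / 40.0) - 1.1 * (cc / 150.0) ** 2
        ),
    }


@dataclass
class TruthBundle:
    """Ground-truth parameters generating one synthetic study."""

    detection_sigma_by_bss: dict = field(default_factory=lambda: dict(SIGMA_BY_BSS))
    density_response: dict = field(default_factory=_default_density_response)
    bss_probs: dict = field(default_factory=lambda: dict(BSS_PROBS))
    design: SurveyDesign = field(default_factory=SurveyDesign)
    truncation_m: float = 1000.0
    nb_size: float | None = 2.0   # NB dispersion; None -> Poisson counts
    group_size_lambda: float = 0.35  # group size = 1 + Poisson(lambda)
    p_distance_missing: float = 0.18
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.detection_sigma_by_bss.values()):
            raise ValueError("detection sigma must be positive")

    def log_density(self, table: pd.DataFrame) -> np.ndarray:
        """Log of true whale density (whales/km^2) at covariate rows."""
        eta = np.full(len(table), float(self.density_response.get("intercept", 0.0)))
        for key, f in self.density_response.items():
            if key == "intercept":
                continue
            if isinstance(key, tuple):
                if all(k in table.columns for k in key):
                    eta += f(*(table[k].to_numpy(dtype=float) for k in key))
            elif key == "substrate":
                if "substrate" in table.columns:
                    eta += table["substrate"].map(f).fillna(0.0).to_numpy(dtype=float)
            elif key in table.columns:
                eta += f(table[key].to_numpy(dtype=float))
        return eta


# ---------------------------------------------------------------------------
# physical environment generators


def make_coastline(
    n_capes: int = 2,
    n_estuaries: int = 3,
    seed: int = 0,
    length_km: float = 400.0,
    lat0: float = 40.0,
    cape_amplitude: float = 10.0,
    cape_width: float = 15.0,
    spacing_km: float = 0.5,
) -> Coastline:
    """A north-south coastline with Gaussian-bump capes and estuary points.

    Capes protrude ``cape_amplitude`` km seaward over an alongshore scale of
    ``cape_width`` km, sized so each deviates by more than 5 km from the
    200-km-smoothed coastline; estuaries are shore points with surface areas
    drawn above 300 ha.
    """
    if n_capes < 0 or n_estuaries < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    y = np.arange(0.0, length_km + spacing_km / 2, spacing_km)
    x = np.zeros_like(y)
    # gentle large-scale curvature so the coast is not perfectly straight
    x += 1.5 * np.sin(2 * np.pi * y / length_km)
    if n_capes > 0:
        # one cape per evenly spaced alongshore slot, jittered, so capes
        # stay well separated and clear of the coastline ends
        slots = np.linspace(0.2, 0.8, n_capes) * length_km
        jitter = rng.uniform(-0.25, 0.25, size=n_capes) * (
            (0.6 * length_km) / max(n_capes, 2)
        )
        for c in slots + jitter:
            x -= cape_amplitude * np.exp(-(((y - c) / cape_width) ** 2))
    estuaries = []
    for k in range(n_estuaries):
        ey = rng.uniform(0.05 * length_km, 0.95 * length_km)
        estuaries.append(
            {
                "x": float(np.interp(ey, y, x)),
                "y": float(ey),
                "area_ha": float(rng.uniform(320.0, 5000.0)),
            }
        )
    return Coastline(y=y, shore_x=x, lat0=lat0, estuaries=estuaries)


def default_shelf_profile(dist_km, lat):
    """Depth (m) vs offshore distance, 200 m isobath at 9-21 km by latitude."""
    w200 = 15.0 + 6.0 * np.sin(2.0 * np.pi * (np.asarray(lat) - 40.0) / 3.0)
    return 200.0 * np.asarray(dist_km) / w200


def make_bathymetry(
    coastline: Coastline,
    shelf_profile: Callable = default_shelf_profile,
    cell: float = 1.0,
    max_offshore: float = 35.0,
) -> Raster:
    """Depth raster from a monotone cross-shore profile.

    ``shelf_profile(dist_km, lat)`` (or ``shelf_profile(dist_km)``) gives
    depth in metres at each offshore distance; it must be non-decreasing in
    distance.  Land cells (onshore of the coastline) are NaN.
    """
    test_d = np.linspace(0.0, max_offshore, 50)
    try:
        prof = np.asarray(shelf_profile(test_d, coastline.lat0), dtype=float)
        two_arg = True
    except TypeError:
        prof = np.asarray(shelf_profile(test_d), dtype=float)
        two_arg = False
    if np.any(np.diff(prof) < -1e-9):
        raise ValueError("shelf profile must be monotone in offshore distance")
    x0 = float(coastline.shore_x.min() - max_offshore)
    x1 = float(coastline.shore_x.max() + 2.0)
    xs = np.arange(x0, x1 + cell / 2, cell)
    ys = np.arange(coastline.y[0], coastline.y[-1] + cell / 2, cell)
    shore = coastline.shore_at(ys)
    dist = shore[:, None] - xs[None, :]  # km offshore (positive in ocean)
    lat = coastline.lat_of(ys)[:, None]
    if two_arg:
        depth = shelf_profile(np.maximum(dist, 0.0), lat)
    else:
        depth = shelf_profile(np.maximum(dist, 0.0))
    depth = np.where(dist > 0, depth, np.nan)
    return Raster(values=depth, x0=xs[0], y0=ys[0], cell=cell)


def _random_smooth_field(xs, ys, rng, patch_scale: float) -> np.ndarray:
    """Smooth random field as a sum of random 2-D waves, roughly N(0, 1)."""
    f = np.zeros((ys.size, xs.size))
    for _ in range(8):
        ky = rng.uniform(0.2, 1.0) * 2 * np.pi / patch_scale
        kx = rng.uniform(0.2, 1.0) * 2 * np.pi / patch_scale
        ph = rng.uniform(0, 2 * np.pi, size=2)
        f += rng.normal() * np.sin(ky * ys[:, None] + ph[0]) * np.sin(
            kx * xs[None, :] + ph[1]
        )
    return f / 2.0


def make_substrate(
    coastline: Coastline,
    seed: int = 0,
    cell: float = 1.0,
    max_offshore: float = 35.0,
    hard_fraction: float = 0.35,
    patch_scale: float = 12.0,
) -> Raster:
    """Binary hard(1)/soft(0) substrate raster with alongshore patchiness."""
    rng = np.random.default_rng(seed)
    x0 = float(coastline.shore_x.min() - max_offshore)
    x1 = float(coastline.shore_x.max() + 2.0)
    xs = np.arange(x0, x1 + cell / 2, cell)
    ys = np.arange(coastline.y[0], coastline.y[-1] + cell / 2, cell)
    f = _random_smooth_field(xs, ys, rng, patch_scale)
    thr = np.quantile(f, 1.0 - hard_fraction)
    return Raster(values=(f > thr).astype(float), x0=xs[0], y0=ys[0], cell=cell)


def roughen_bathymetry(depth: Raster, seed: int = 0,
                       relative_sd: float = 0.35,
                       patch_scale: float = 25.0) -> Raster:
    """Multiply depth by a smooth random field: reefs, banks, gullies.

    Without this, depth would be an exact function of distance-to-coast and
    shelf width, and the additive model could not attribute effects among
    the collinear covariates.
    """
    rng = np.random.default_rng(seed)
    f = _random_smooth_field(depth.x_coords, depth.y_coords, rng, patch_scale)
    vals = depth.values * np.clip(1.0 + relative_sd * f, 0.3, 2.0)
    return Raster(values=vals, x0=depth.x0, y0=depth.y0, cell=depth.cell)


def make_cuti_series(
    years,
    amplitude: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    lat_bins=(40.5, 41.5, 42.5, 43.5),
) -> pd.DataFrame:
    """Daily CUTI per 1-degree latitude bin: seasonal sinusoid plus noise.

    Negative in winter, positive in summer (upwelling season), with a small
    northward weakening of amplitude; reproducible by seed.
    """
    years = list(years)
    if not years:
        raise ValueError("years must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for lat_bin in lat_bins:
        amp = amplitude * (1.0 - 0.08 * (lat_bin - 42.0))
        for yr in years:
            dates = pd.date_range(f"{yr}-01-01", f"{yr}-12-31", freq="D")
            doy = dates.dayofyear.to_numpy()
            base = -amp * np.cos(2.0 * np.pi * (doy - 15) / 365.0)
            vals = base + rng.normal(0.0, noise_sd, size=doy.size)
            rows.append(
                pd.DataFrame({"date": dates, "lat_bin": lat_bin, "cuti": vals})
            )
    return pd.concat(rows, ignore_index=True)


def make_sst_series(
    years,
    lat_grid=None,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Daily SST (deg C) on a 0.25-degree latitude grid: seasonal + noise.

    The anomaly scale reflects the 1-2 deg C mesoscale variability of
    nearshore upwelling systems; it is what makes the SST effect separable
    from the (equally seasonal) cumulative upwelling indices.
    """
    years = list(years)
    rng = np.random.default_rng(seed)
    if lat_grid is None:
        lat_grid = np.arange(40.0, 43.76, 0.25)
    rows = []
    for lat in lat_grid:
        for yr in years:
            dates = pd.date_range(f"{yr}-01-01", f"{yr}-12-31", freq="D")
            doy = dates.dayofyear.to_numpy()
            base = (
                11.0
                + 3.0 * np.sin(2.0 * np.pi * (doy - 120) / 365.0)
                + 0.4 * (43.0 - lat)
            )
            rows.append(
                pd.DataFrame(
                    {
                        "date": dates,
                        "lat": round(float(lat), 3),
                        "sst": base + rng.normal(0.0, noise_sd, size=doy.size),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# environment bundle


@dataclass
class SyntheticEnvironment:
    """All physical inputs for one synthetic study, ready for extraction."""

    coastline: Coastline
    layers: cov.StaticLayers
    dynamic: pd.DataFrame   # (date, lat_bin) -> cum_cuti, cum_relax
    sst: pd.DataFrame       # (date, lat) -> sst
    years: list
    offshore_break_y: float  # alongshore position of the 5 km / 3 km break
    region_breaks: tuple     # (y_23, y_12): region 3 south, 1 north


def make_environment(
    years,
    seed: int = 0,
    n_capes: int = 2,
    n_estuaries: int = 3,
    length_km: float = 400.0,
    cuti_amplitude: float = 1.0,
    cuti_noise_sd: float = 0.3,
) -> SyntheticEnvironment:
    """Generate the full physical environment for the given years."""
    years = list(years)
    ss = np.random.SeedSequence(seed)
    s_coast, s_sub, s_cuti, s_sst, s_rough = [
        int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(5)
    ]
    coastline = make_coastline(n_capes, n_estuaries, seed=s_coast,
                               length_km=length_km)
    depth = roughen_bathymetry(make_bathymetry(coastline), seed=s_rough)
    substrate = make_substrate(coastline, seed=s_sub)
    layers = cov.StaticLayers.build(depth, substrate, coastline)
    cuti = make_cuti_series(years, amplitude=cuti_amplitude,
                            noise_sd=cuti_noise_sd, seed=s_cuti)
    dynamic = cov.build_dynamic_series(cuti, years=years)
    sst = make_sst_series(years, seed=s_sst)
    return SyntheticEnvironment(
        coastline=coastline,
        layers=layers,
        dynamic=dynamic,
        sst=sst,
        years=years,
        offshore_break_y=0.75 * length_km,
        region_breaks=(0.275 * length_km, 0.65 * length_km),
    )


def _region_of(y: np.ndarray, breaks) -> np.ndarray:
    y23, y12 = breaks
    return np.where(y >= y12, 1, np.where(y >= y23, 2, 3))


def _hn_detect_prob(x: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-(x**2) / (2.0 * sigma**2))


def simulate_halfnormal_distances(n: int, sigma: float, w: float, rng):
    """Perpendicular distances of detected animals under half-normal g.

    Animals are uniform in the strip [0, w] and detected with probability
    exp(-x^2 / 2 sigma^2) (rejection sampling); the accepted distances
    follow the truncated half-normal detection density.
    """
    out = []
    while sum(len(o) for o in out) < n:
        x = rng.uniform(0.0, w, size=4 * n)
        keep = rng.random(4 * n) < _hn_detect_prob(x, sigma)
        out.append(x[keep])
    return np.concatenate(out)[:n]


def build_segment_frame(
    env: SyntheticEnvironment,
    design: SurveyDesign,
    years=None,
    n_sweeps: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Lay out survey segments (no whales yet) following the PSU design."""
    years = list(years) if years is not None else env.years
    rng = np.random.default_rng(seed)
    coast = env.coastline
    length_km = coast.y[-1]
    n_psu = int(length_km // design.psu_length)
    # sweep start days; with the per-PSU stagger below, effort spans
    # roughly 16 May - 27 Aug, matching the seasonal survey window
    sweep_doys = np.linspace(136, 222, n_sweeps).round().astype(int)
    bss_levels = np.array(sorted(BSS_PROBS))
    bss_p = np.array([BSS_PROBS[k] for k in bss_levels])
    sight_levels = list(SIGHTABILITY_PROBS)
    sight_p = np.array(list(SIGHTABILITY_PROBS.values()))
    rows = []
    for yr in years:
        for sweep, doy in enumerate(sweep_doys):
            for p in range(n_psu):
                # PSUs are worked through over ~2.5 weeks per sweep, so
                # effort is spread across the season rather than pulsed
                day_off = int(rng.integers(0, 18)) if n_psu > 1 else 0
                date = pd.Timestamp(f"{yr}-01-01") + pd.Timedelta(
                    int(doy) - 1 + day_off, "D"
                )
                psu_y0 = p * design.psu_length
                psu_id = f"PSU{p:02d}"
                bss = int(rng.choice(bss_levels, p=bss_p))
                sight = str(rng.choice(sight_levels, p=sight_p))
                # four inshore segments at random distances < 1500 m offshore
                slots = rng.permutation(design.n_inshore_per_psu)
                for s in range(design.n_inshore_per_psu):
                    cy = psu_y0 + (slots[s] + 0.5) * (
                        design.psu_length / design.n_inshore_per_psu
                    )
                    off_km = rng.uniform(0.15, design.inshore_max_dist / 1000.0)
                    cx = float(coast.shore_at(cy)) - off_km
                    rows.append(
                        dict(
                            segment_id=f"{yr}-{sweep}-{psu_id}-I{s}",
                            psu_id=psu_id, kind="inshore", date=date,
                            region=int(_region_of(np.array([cy]), env.region_breaks)[0]),
                            length_km=design.inshore_segment_length,
                            x=cx, y=float(cy), bearing_deg=0.0,
                            bss=bss, sightability=sight,
                        )
                    )
                # the diagonal offshore transect runs from the inshore
                # boundary out to the offshore limit; it is analysed as two
                # segments whose centroids fall in the inner and outer half
                # of the band, so cross-shore coverage spans the full band
                limit = (
                    design.offshore_limit_north
                    if psu_y0 >= env.offshore_break_y
                    else design.offshore_limit_south
                )
                inner = design.inshore_max_dist / 1000.0
                mid = (inner + limit) / 2.0
                total = float(rng.uniform(*design.offshore_length_range))
                for j, (b0, b1) in enumerate([(inner, mid), (mid, limit)]):
                    cy = psu_y0 + rng.uniform(0.15, 0.85) * design.psu_length
                    cx = float(coast.shore_at(cy)) - rng.uniform(
                        b0 + 0.1, b1 - 0.1
                    )
                    rows.append(
                        dict(
                            segment_id=f"{yr}-{sweep}-{psu_id}-O{j}",
                            psu_id=psu_id, kind="offshore", date=date,
                            region=int(_region_of(np.array([cy]), env.region_breaks)[0]),
                            length_km=total / 2.0, x=cx, y=float(cy),
                            bearing_deg=40.0, bss=bss, sightability=sight,
                        )
                    )
    seg = pd.DataFrame(rows)
    seg["lat"] = coast.lat_of(seg["y"].to_numpy())
    seg["lon"] = -124.0 + seg["x"].to_numpy() / (KM_PER_DEG * 0.74)
    return seg


def simulate_survey(
    truth: TruthBundle,
    env: SyntheticEnvironment,
    years=None,
    seed: int = 0,
    n_sweeps: int = 4,
    perfect_detection: bool = False,
):
    """Simulate one survey programme; returns (segments, sightings) tables.

    Per segment, the number of whale groups in the truncation-free strip is
    drawn negative-binomially (Poisson when ``truth.nb_size`` is None) with
    mean density x 2w x length / E[group size]; each group gets a uniform
    perpendicular distance in [0, w] and is sighted with half-normal
    probability at the segment's true BSS sigma.  Detected groups become
    sightings; ``n_whales`` sums their sizes.
    """
    rng = np.random.default_rng(seed)
    seg = build_segment_frame(env, truth.design, years=years,
                              n_sweeps=n_sweeps, seed=seed)
    segcov = cov.extract_at_segments(env.layers, env.dynamic, env.sst, seg)
    w_km = truth.truncation_m / 1000.0
    eta = truth.log_density(segcov)
    mean_gs = 1.0 + truth.group_size_lambda
    mu_groups = np.exp(eta) * 2.0 * w_km * segcov["length_km"].to_numpy() / mean_gs
    if truth.nb_size is None:
        n_groups = rng.poisson(mu_groups)
    else:
        th = truth.nb_size
        n_groups = rng.negative_binomial(th, th / (th + mu_groups))
    sight_rows = []
    n_whales = np.zeros(len(segcov), dtype=int)
    sid = 0
    for i, row in enumerate(segcov.itertuples()):
        k = int(n_groups[i])
        if k == 0:
            continue
        x = rng.uniform(0.0, truth.truncation_m, size=k)
        sigma = truth.detection_sigma_by_bss[int(row.bss)]
        p = np.ones(k) if perfect_detection else _hn_detect_prob(x, sigma)
        detected = rng.random(k) < p
        sizes = 1 + rng.poisson(truth.group_size_lambda, size=k)
        for xj, sj in zip(x[detected], sizes[detected]):
            missing = rng.random() < truth.p_distance_missing
            sight_rows.append(
                dict(
                    sighting_id=f"S{sid:06d}",
                    segment_id=row.segment_id,
                    date=row.date,
                    lat=row.lat,
                    lon=row.lon,
                    perp_distance_m=(np.nan if missing else float(xj)),
                    group_size=int(sj),
                    bss=int(row.bss),
                    sightability=row.sightability,
                )
            )
            sid += 1
        n_whales[i] = sizes[detected].sum()
    segcov = segcov.copy()
    segcov["n_whales"] = n_whales
    sightings = pd.DataFrame(
        sight_rows,
        columns=[
            "sighting_id", "segment_id", "date", "lat", "lon",
            "perp_distance_m", "group_size", "bss", "sightability",
        ],
    )
    return segcov, sightings


def true_abundance(
    truth: TruthBundle,
    env: SyntheticEnvironment,
    grid_covariates: pd.DataFrame,
) -> pd.DataFrame:
    """True whale abundance per region-day on a covariate-attached grid.

    ``grid_covariates`` is the long per-cell-per-day table produced by the
    prediction module; abundance is area x exp(true log density) summed
    over cells.
    """
    g = grid_covariates.copy()
    eta = truth.log_density(g)
    g["N_true"] = g["area_km2"].to_numpy() * np.exp(eta)
    return (
        g.groupby(["region", "date"], as_index=False)["N_true"].sum()
    )
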