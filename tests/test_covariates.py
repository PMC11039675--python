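import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nearshoredsm import covariates as cov
from nearshoredsm import synthetic
from nearshoredsm._geo import Coastline, Raster


def straight_coast(length=400.0, spacing=0.5):
    y = np.arange(0.0, length + spacing / 2, spacing)
    return Coastline(y=y, shore_x=np.zeros_like(y))


# ---------------------------------------------------------------------------
# shelf width


def test_shelf_width_linear_profile():
    """A 20 m/km shelf puts the 200 m isobath at 10 km everywhere."""
    c = straight_coast(100.0)
    depth = synthetic.make_bathymetry(c, lambda d: 20.0 * d, cell=0.5)
    table = cov.shelf_width(depth, c)
    ok = table[~table["missing"]]
    assert np.allclose(ok["shelf_width_km"], 10.0, atol=depth.cell)


def test_shelf_width_controllable_per_latitude():
    c = straight_coast(200.0)
    depth = synthetic.make_bathymetry(c, lambda d: 200.0 * d / 12.0, cell=0.5)
    table = cov.shelf_width(depth, c)
    ok = table[~table["missing"]]
    assert np.allclose(ok["shelf_width_km"], 12.0, atol=depth.cell)


def test_shelf_width_all_shallow_flagged():
    c = straight_coast(50.0)
    depth = synthetic.make_bathymetry(c, lambda d: 2.0 * d)  # never 200 m
    table = cov.shelf_width(depth, c)
    assert table["missing"].all()
    with pytest.raises(ValueError):
        cov.shelf_width_at(table, [10.0])


# ---------------------------------------------------------------------------
# capes


def test_straight_coastline_has_no_capes():
    assert cov.detect_capes(straight_coast()) == []


def test_single_protrusion_detected_at_apex():
    c = straight_coast()
    x = c.shore_x - 10.0 * np.exp(-(((c.y - 200.0) / 15.0) ** 2))
    c2 = Coastline(y=c.y, shore_x=x)
    capes = cov.detect_capes(c2)
    assert len(capes) == 1
    assert abs(capes[0].y - 200.0) < 2.0


def test_subthreshold_protrusion_ignored():
    c = straight_coast()
    x = c.shore_x - 4.0 * np.exp(-(((c.y - 200.0) / 15.0) ** 2))
    assert cov.detect_capes(Coastline(y=c.y, shore_x=x)) == []


def test_short_coastline_rejected():
    with pytest.raises(ValueError):
        cov.detect_capes(straight_coast(100.0))


def test_dist_cape_sign_convention_and_tie():
    capes = [cov.Cape(x=0.0, y=100.0, lat=41.0, deviation_km=8.0)]
    d = cov.dist_cape([0.0, 0.0], [110.0, 90.0], capes)
    assert d[0] == pytest.approx(-10.0)  # north of the cape
    assert d[1] == pytest.approx(10.0)   # south of the cape
    # equidistant between two capes: lower-index cape wins
    two = capes + [cov.Cape(x=0.0, y=120.0, lat=41.2, deviation_km=8.0)]
    d = cov.dist_cape([0.0], [110.0], two)
    assert d[0] == pytest.approx(-10.0)  # north of cape 0, not south of cape 1


def test_dist_cape_requires_capes():
    with pytest.raises(ValueError):
        cov.dist_cape([0.0], [0.0], [])


def test_dist_cape_sign_flips_across_cape():
    capes = [cov.Cape(x=0.0, y=50.0, lat=40.5, deviation_km=9.0)]
    ys = np.linspace(30.0, 70.0, 9)
    d = cov.dist_cape(np.zeros_like(ys), ys, capes)
    assert (d[ys < 50.0] > 0).all() and (d[ys > 50.0] < 0).all()


# ---------------------------------------------------------------------------
# estuaries and substrate


def test_dist_estuary_filters_small_and_measures():
    est = [
        {"x": 0.0, "y": 10.0, "area_ha": 200.0},   # too small, dropped
        {"x": 0.0, "y": 20.0, "area_ha": 500.0},
    ]
    d = cov.dist_estuary([0.0], [15.0], est)
    assert d[0] == pytest.approx(5.0)
    with pytest.raises(ValueError):
        cov.dist_estuary([0.0], [15.0], est[:1])
    assert cov.dist_estuary([0.0], [20.0], est)[0] == 0.0


@pytest.mark.parametrize(
    "field, expected",
    [
        (np.ones((10, 10)), "hard"),
        (np.zeros((10, 10)), "soft"),
    ],
)
def test_substrate_uniform_footprint(field, expected):
    r = Raster(values=field, x0=0.0, y0=0.0, cell=1.0)
    assert cov.substrate_of_segment(5.0, 5.0, 5.0, r) == expected


def test_substrate_majority_and_tie_rules():
    vals = np.zeros((10, 10))
    vals[:, :4] = 1.0  # 40% hard along a northward segment at x=2 -> hard col
    r = Raster(values=vals, x0=0.0, y0=0.0, cell=1.0)
    # segment footprint entirely in hard columns
    assert cov.substrate_of_segment(2.0, 5.0, 4.0, r) == "hard"
    # tie: footprint spanning equal hard/soft cells -> soft
    vals2 = np.zeros((1, 10))
    vals2[0, :5] = 1.0
    r2 = Raster(values=vals2, x0=0.0, y0=0.0, cell=1.0)
    out = cov.substrate_of_segment(4.5, 0.0, 9.0, r2, bearing_deg=90.0)
    assert out == "soft"


def test_substrate_outside_raster_missing():
    r = Raster(values=np.ones((4, 4)), x0=0.0, y0=0.0, cell=1.0)
    assert cov.substrate_of_segment(50.0, 50.0, 5.0, r) is None


# ---------------------------------------------------------------------------
# CUTI smoothing and phenology


def daily_frame(values, year=2001, lat_bin=41.5):
    dates = pd.date_range(f"{year}-01-01", periods=len(values), freq="D")
    return pd.DataFrame({"date": dates, "lat_bin": lat_bin, "cuti": values})


def test_smooth_cuti_constant_series_unchanged():
    out = cov.smooth_cuti(daily_frame(np.full(60, 2.5)))
    np.testing.assert_allclose(out["cuti_smoothed"], 2.5)


def test_smooth_cuti_spike_spread_to_window_mean():
    v = np.zeros(60)
    v[30] = 7.0
    out = cov.smooth_cuti(daily_frame(v))
    assert out["cuti_smoothed"].max() == pytest.approx(0.7)


def test_smooth_cuti_ramp_interior_near_identity():
    v = np.arange(60, dtype=float)
    out = cov.smooth_cuti(daily_frame(v))["cuti_smoothed"].to_numpy()
    # even window centring offsets a pure ramp by half a step
    assert np.allclose(out[10:50], v[10:50] - 0.5)


def test_smooth_cuti_gaps_rejected():
    f = daily_frame(np.zeros(30))
    f = f.drop(index=10)
    with pytest.raises(ValueError, match="gaps"):
        cov.smooth_cuti(f)


def sinusoid_year(year=2001, lat_bin=41.5, amp=1.0):
    dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    vals = -amp * np.cos(2 * np.pi * (doy - 15) / 365.0)
    return pd.DataFrame(
        {"date": dates, "lat_bin": lat_bin, "cuti": vals,
         "cuti_smoothed": vals}
    )


def test_phenology_sinusoid_transition_at_sign_change():
    """Cumulative minimum of a sinusoid sits where it crosses zero upward."""
    sm = sinusoid_year()
    p = cov.upwelling_phenology(sm, 2001, 41.5)
    # -cos(2 pi (doy-15)/365) crosses zero upward at doy = 15 + 365/4
    expect = pd.Timestamp("2001-01-01") + pd.Timedelta(int(15 + 365 / 4) - 1, "D")
    assert abs((p.spring_transition - expect).days) <= 2
    assert p.spring_transition < p.season_end
    assert not p.degenerate


def test_phenology_shift_equivariance():
    sm = sinusoid_year()
    shifted = sm.copy()
    doy = pd.to_datetime(shifted["date"]).dt.dayofyear.to_numpy()
    vals = -np.cos(2 * np.pi * (doy - 45) / 365.0)
    shifted["cuti_smoothed"] = vals
    p0 = cov.upwelling_phenology(sm, 2001, 41.5)
    p1 = cov.upwelling_phenology(shifted, 2001, 41.5)
    assert abs((p1.spring_transition - p0.spring_transition).days - 30) <= 2


def test_phenology_all_positive_year_flagged():
    sm = sinusoid_year()
    sm["cuti_smoothed"] = 1.0
    p = cov.upwelling_phenology(sm, 2001, 41.5)
    assert p.degenerate
    assert p.spring_transition == pd.Timestamp("2001-01-01")


def test_cumulative_cuti_zero_at_transition_and_linear_for_constant():
    sm = sinusoid_year()
    p = cov.upwelling_phenology(sm, 2001, 41.5)
    sm2 = sm.copy()
    sm2["cuti_smoothed"] = 2.0
    cc = cov.cumulative_cuti(sm2, p)
    assert cc.loc[p.spring_transition] == 0.0
    after = cc.index > p.spring_transition
    days_since = (cc.index[after] - p.spring_transition).days
    np.testing.assert_allclose(cc[after], 2.0 * days_since)
    assert (cc[cc.index < p.spring_transition] == 0).all()


def test_relaxation_threshold_examples():
    sm = sinusoid_year()
    p = cov.upwelling_phenology(sm, 2001, 41.5)
    smc = sm.copy()
    smc["cuti_smoothed"] = 3.0
    assert cov.relaxation_threshold(smc, [p], 41.5) == pytest.approx(3.0)
    # constant series: nothing is strictly below the mean
    cr = cov.cumulative_relaxation(smc, 3.0, p)
    assert (cr == 0).all()


def test_relaxation_threshold_pools_equal_length_seasons():
    sm1 = sinusoid_year(2001)
    sm2 = sinusoid_year(2002)
    p1 = cov.upwelling_phenology(sm1, 2001, 41.5)
    p2 = cov.upwelling_phenology(sm2, 2002, 41.5)
    sm1["cuti_smoothed"] = 1.0
    sm2["cuti_smoothed"] = 3.0
    both = pd.concat([sm1, sm2], ignore_index=True)
    thr = cov.relaxation_threshold(both, [p1, p2], 41.5)
    assert thr == pytest.approx(2.0, abs=0.01)


def test_cumulative_relaxation_alternating_series():
    sm = sinusoid_year()
    p = cov.upwelling_phenology(sm, 2001, 41.5)
    alt = sm.copy()
    vals = np.where(np.arange(len(alt)) % 2 == 0, -1.0, 1.0)
    alt["cuti_smoothed"] = vals
    cr = cov.cumulative_relaxation(alt, 0.0, p)
    after = cr.index > p.spring_transition
    steps = np.diff(cr[after].to_numpy())
    assert set(steps) <= {0.0, 1.0}
    # every other post-transition day is below threshold
    n_after = int(after.sum())
    assert cr.iloc[-1] == pytest.approx(n_after / 2, abs=1)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_cumulative_relaxation_matches_brute_force(seed):
    """Vectorised relaxation counting equals day-by-day counting."""
    rng = np.random.default_rng(seed)
    sm = sinusoid_year()
    sm["cuti_smoothed"] = rng.normal(0.2, 1.0, size=len(sm))
    p = cov.upwelling_phenology(sm, 2001, 41.5)
    thr = cov.relaxation_threshold(sm, [p], 41.5)
    cr = cov.cumulative_relaxation(sm, thr, p)
    # brute force: loop over days
    count = 0
    for d, v in zip(pd.to_datetime(sm["date"]), sm["cuti_smoothed"]):
        if d > p.spring_transition and v < thr:
            count += 1
        if d >= p.spring_transition:
            assert cr.loc[d] == count
    # brute-force threshold
    dates = pd.to_datetime(sm["date"])
    in_season = (dates > p.spring_transition) & (dates <= p.season_end)
    assert thr == pytest.approx(sm.loc[in_season.values, "cuti_smoothed"].mean())


def test_cum_relax_bounded_by_days_since_transition():
    dyn = cov.build_dynamic_series(
        synthetic.make_cuti_series([2003], seed=5, lat_bins=(41.5,))
    )
    trans = dyn["spring_transition"].iloc[0]
    days = (pd.to_datetime(dyn["date"]) - trans).dt.days.clip(lower=0)
    assert (dyn["cum_relax"] <= days).all()


# ---------------------------------------------------------------------------
# extraction


def test_extract_at_segments_known_values(small_env):
    env = small_env
    seg = pd.DataFrame(
        {
            "segment_id": ["a", "b"],
            "date": [pd.Timestamp("2001-06-15")] * 2,
            "x": [env.coastline.shore_at(50.0) - 1.0] * 2,
            "y": [50.0, 50.0],
            "length_km": [5.0, 5.0],
        }
    )
    out = cov.extract_at_segments(env.layers, env.dynamic, env.sst, seg)
    assert len(out) == 2
    # same centroid/date: identical dynamic covariates
    assert out["cum_cuti"].iloc[0] == out["cum_cuti"].iloc[1]
    assert out["cum_relax"].iloc[0] == out["cum_relax"].iloc[1]
    assert out["dist_coast"].iloc[0] == pytest.approx(1.0)
    assert np.isfinite(out[["depth", "sst", "shelf_width", "dist_estuary"]]).all().all()


def test_extract_drops_out_of_raster_segments(small_env):
    env = small_env
    seg = pd.DataFrame(
        {
            "segment_id": ["far"],
            "date": [pd.Timestamp("2001-06-15")],
            "x": [500.0],
            "y": [50.0],
            "length_km": [5.0],
        }
    )
    log = []
    out = cov.extract_at_segments(env.layers, env.dynamic, env.sst, seg, log=log)
    assert len(out) == 0
    assert any("outside raster" in m for m in log)


def test_pre_transition_dates_have_zero_cumulative(small_env):
    env = small_env
    dyn = env.dynamic
    pre = dyn[pd.to_datetime(dyn["date"]) < dyn["spring_transition"]]
    assert (pre["cum_cuti"] == 0).all()
    assert (pre["cum_relax"] == 0).all()
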