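"""Climate-oscillation correlates of annual predicted abundance.

Relates the annual abundance series to basin-scale climate indices (PDO,
MEI): seasonal means (spring = February-May, summer = May-August; May is
in both), lagged cross-correlations up to 10 years, ordinary least squares
regressions reporting R^2 and F(1, n-2), and rolling standard deviations
of an index over the preceding 1-5 years.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

SEASONS = {"spring": (2, 3, 4, 5), "summer": (5, 6, 7, 8)}


def seasonal_mean(series: pd.DataFrame, season: str, year: int) -> float:
    """Arithmetic mean of the index over the season's months of one year.

    ``series`` has columns (index, year, month, value) or (year, month,
    value).  All four months must be present.
    """
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}")
    months = SEASONS[season]
    sub = series[(series["year"] == year) & (series["month"].isin(months))]
    if len(sub) != len(months):
        got = sorted(sub["month"].unique())
        raise ValueError(
            f"season {season} {year}: need months {months}, have {got}"
        )
    return float(sub["value"].mean())


def seasonal_series(series: pd.DataFrame, season: str) -> pd.DataFrame:
    """Seasonal means for every year with complete coverage."""
    rows = []
    for yr in sorted(series["year"].unique()):
        try:
            rows.append((yr, seasonal_mean(series, season, yr)))
        except ValueError:
            continue
    return pd.DataFrame(rows, columns=["year", "value"])


def cross_correlation(
    abundance: pd.DataFrame,
    index: pd.DataFrame,
    max_lag: int = 10,
) -> pd.DataFrame:
    """Pearson correlation of abundance(t) with index(t - lag), lag 0..max.

    Both inputs are annual (year, value) frames; series are demeaned over
    each lag's overlapping pairs (plain correlation, no prewhitening).  The
    reference band +-2/sqrt(n) accompanies each lag.
    """
    a = abundance.set_index("year")["value"]
    b = index.set_index("year")["value"]
    span = len(set(a.index) & set(b.index))
    if span < max_lag + 3:
        raise ValueError(
            f"only {span} overlapping years for max_lag={max_lag}"
        )
    rows = []
    for lag in range(max_lag + 1):
        shifted = pd.Series(b.values, index=b.index + lag)
        pairs = pd.concat([a, shifted], axis=1, join="inner").dropna()
        if len(pairs) < 3:
            rows.append((lag, np.nan, len(pairs), np.nan))
            continue
        r = float(np.corrcoef(pairs.iloc[:, 0], pairs.iloc[:, 1])[0, 1])
        rows.append((lag, r, len(pairs), 2.0 / np.sqrt(len(pairs))))
    return pd.DataFrame(rows, columns=["lag", "r", "n", "ref_band"])


def lagged_regression(
    abundance: pd.DataFrame, predictor: pd.DataFrame, lag: int = 0
) -> dict:
    """OLS of abundance on the lag-shifted predictor.

    Returns slope, intercept, R^2, the F statistic with its (1, n-2)
    degrees of freedom, and the two-sided p-value.
    """
    a = abundance.set_index("year")["value"]
    b = predictor.set_index("year")["value"]
    shifted = pd.Series(b.values, index=b.index + lag)
    pairs = pd.concat([a, shifted], axis=1, join="inner").dropna()
    n = len(pairs)
    if n < 4:
        raise ValueError(f"need at least 4 paired years, have {n}")
    x = pairs.iloc[:, 1].to_numpy()
    y = pairs.iloc[:, 0].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor")
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    f = (res.slope / res.stderr) ** 2 if res.stderr > 0 else np.inf
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(r2),
        "f": float(f),
        "df": (1, n - 2),
        "p": float(res.pvalue),
        "n": n,
    }


def rolling_sd(index: pd.DataFrame, window: int) -> pd.DataFrame:
    """Sample sd of the index over the ``window`` years strictly preceding.

    Years with insufficient history are missing; a window of 1 yields sd 0
    by convention (flagged in the ``degenerate`` column).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    s = index.sort_values("year").set_index("year")["value"]
    years = s.index.to_numpy()
    rows = []
    for yr in years:
        prior = s.loc[(s.index >= yr - window) & (s.index < yr)]
        if len(prior) < window:
            continue
        sd = 0.0 if window == 1 else float(prior.std(ddof=1))
        rows.append((yr, sd))
    out = pd.DataFrame(rows, columns=["year", "sd"])
    out["degenerate"] = window == 1
    return out


def make_climate_index(
    years, seed: int = 0, name: str = "PDO", ar: float = 0.6, sd: float = 1.0
) -> pd.DataFrame:
    """A synthetic monthly climate index: AR(1) noise at monthly scale."""
    rng = np.random.default_rng(seed)
    rows = []
    v = rng.normal(0, sd)
    for yr in years:
        for m in range(1, 13):
            v = ar * v + rng.normal(0, sd * np.sqrt(1 - ar**2))
            rows.append((name, yr, m, v))
    return pd.DataFrame(rows, columns=["index", "year", "month", "value"])
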