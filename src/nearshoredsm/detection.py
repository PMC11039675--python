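"""Line-transect detection functions.

Fits truncated detection functions g(x) to perpendicular sighting
distances, with observation-condition covariates (Beaufort sea state,
sightability) entering the scale parameter through a log-linear predictor:

* half-normal key:  g(x) = exp(-x^2 / (2 sigma^2))
* hazard-rate key:  g(x) = 1 - exp(-(x / sigma)^-b),  b >= 1

Each observation contributes g(x; sigma(z)) / integral_0^w g(u; sigma(z)) du
to the likelihood, where w is the truncation distance (here the 98th
percentile of observed distances, optionally rounded).  Candidate models
are compared by AIC, and the fitted function yields the effective strip
width ESW = integral_0^w g — in closed form via the Gaussian error
integral for the half-normal, by adaptive quadrature for the hazard rate.
Availability at the surface is taken as 1 (slow vessel, short dive times),
so no availability correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special, stats

_SQRT2 = np.sqrt(2.0)
_SQRT_HALF_PI = np.sqrt(np.pi / 2.0)


def truncation_distance(
    distances, percentile: float = 98.0, round_to: float | None = None
) -> float:
    """Truncation distance w as an empirical percentile of distances.

    Uses the linear-interpolation order-statistic definition.  ``round_to``
    rounds the result to the nearest stated multiple (the field convention
    of quoting a round number, e.g. 1000 m).
    """
    d = np.asarray(distances, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < 20:
        raise ValueError(f"need at least 20 distances, got {d.size}")
    w = float(np.percentile(d, percentile))
    if round_to is not None:
        w = round(w / round_to) * round_to
    if w <= 0:
        raise ValueError("non-positive truncation distance")
    return w


def _hn_integral(sigma, w):
    """integral_0^w exp(-x^2 / 2 sigma^2) dx, closed form."""
    sigma = np.asarray(sigma, dtype=float)
    return sigma * _SQRT_HALF_PI * special.erf(w / (sigma * _SQRT2))


def _hr_g(x, sigma, shape):
    with np.errstate(divide="ignore", over="ignore"):
        return 1.0 - np.exp(-((np.maximum(x, 1e-12) / sigma) ** (-shape)))


def _hr_integral(sigma, w, shape):
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    out = np.empty(sigma.shape)
    for i, s in enumerate(sigma):
        out[i], _ = integrate.quad(_hr_g, 0.0, w, args=(s, shape), limit=200)
    return out


def _design_matrix(covariates: pd.DataFrame | None, n: int):
    """Intercept + treatment-coded categorical levels; returns (X, names)."""
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((n, 1)), ["(Intercept)"]
    X = [np.ones(n)]
    names = ["(Intercept)"]
    for col in covariates.columns:
        vals = covariates[col]
        if isinstance(vals.dtype, pd.CategoricalDtype):
            levels = list(vals.cat.categories)
        else:
            levels = sorted(pd.unique(vals))
        if len(levels) < 2:
            continue  # single level carries no information
        for lev in levels[1:]:
            X.append((vals == lev).to_numpy().astype(float))
            names.append(f"{col}[{lev}]")
    return np.column_stack(X), names


@dataclass
class DetectionFunction:
    """A fitted truncated detection function."""

    key: str  # "half_normal" | "hazard_rate"
    scale_coefficients: np.ndarray  # log-scale linear predictor
    coef_names: list
    truncation_w: float
    loglik: float
    aic: float
    n_obs: int
    shape: float | None = None  # hazard-rate exponent
    covariate_levels: dict = field(default_factory=dict)
    vcov: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return len(self.scale_coefficients) + (self.shape is not None)

    def sigma(self, covariate_values: dict | None = None) -> float:
        """Scale sigma(z) = exp(linear predictor) for given covariate levels."""
        eta = self.scale_coefficients[0]
        if covariate_values:
            for name, coef in zip(
                self.coef_names[1:], self.scale_coefficients[1:]
            ):
                col, lev = name[:-1].split("[", 1)
                if col in covariate_values and str(covariate_values[col]) == lev:
                    eta += coef
        return float(np.exp(eta))

    def g(self, x, covariate_values: dict | None = None):
        s = self.sigma(covariate_values)
        x = np.asarray(x, dtype=float)
        if self.key == "half_normal":
            return np.exp(-(x**2) / (2.0 * s**2))
        return _hr_g(x, s, self.shape)

    def cdf(self, x, covariate_values: dict | None = None):
        """Fitted CDF of perpendicular distances on [0, w]."""
        s = self.sigma(covariate_values)
        x = np.clip(np.asarray(x, dtype=float), 0.0, self.truncation_w)
        if self.key == "half_normal":
            return _hn_integral(s, x) / _hn_integral(s, self.truncation_w)
        num = np.array(
            [integrate.quad(_hr_g, 0, xi, args=(s, self.shape))[0] for xi in np.atleast_1d(x)]
        )
        return num / _hr_integral(s, self.truncation_w, self.shape)[0]


def esw(df: DetectionFunction, covariate_values: dict | None = None) -> float:
    """Effective strip width, ESW = integral_0^w g(x; sigma(z)) dx, in metres."""
    s = df.sigma(covariate_values)
    if df.key == "half_normal":
        return float(_hn_integral(s, df.truncation_w))
    return float(_hr_integral(s, df.truncation_w, df.shape)[0])


def hn_esw(sigma: float, w: float) -> float:
    """Closed-form half-normal ESW: sigma sqrt(pi/2) erf(w / (sigma sqrt 2))."""
    return float(_hn_integral(sigma, w))


def fit_detection(
    distances,
    key: str = "half_normal",
    covariates: pd.DataFrame | None = None,
    w: float | None = None,
    n_starts: int = 3,
    seed: int = 0,
) -> DetectionFunction:
    """Maximum-likelihood fit of a truncated detection function.

    ``distances`` are perpendicular distances in metres (observations
    beyond ``w`` are excluded; missing distances must be dropped upstream).
    ``covariates`` is an optional frame of categorical columns aligned with
    ``distances``; each level offsets log(sigma).
    """
    if key not in ("half_normal", "hazard_rate"):
        raise ValueError(f"unknown key {key!r}")
    d = np.asarray(distances, dtype=float)
    keep = np.isfinite(d)
    if covariates is not None:
        covariates = covariates.reset_index(drop=True)
    if w is None:
        w = truncation_distance(d[keep])
    inside = keep & (d <= w)
    d = d[inside]
    if covariates is not None:
        covariates = covariates.loc[np.flatnonzero(inside)].reset_index(drop=True)
    n = d.size
    if n < 10:
        raise ValueError(f"too few observations inside truncation ({n})")
    X, names = _design_matrix(covariates, n)
    p_scale = X.shape[1]
    has_shape = key == "hazard_rate"

    def negloglik(theta):
        beta = theta[:p_scale]
        sigma = np.exp(np.clip(X @ beta, -10, 12))
        if key == "half_normal":
            g = np.exp(-(d**2) / (2.0 * sigma**2))
            mu = _hn_integral(sigma, w)
        else:
            shape = 1.0 + np.exp(theta[-1])
            g = _hr_g(d, sigma, shape)
            uniq, inv = np.unique(sigma, return_inverse=True)
            mu = _hr_integral(uniq, w, shape)[inv]
        with np.errstate(divide="ignore"):
            ll = np.log(np.maximum(g, 1e-300)) - np.log(np.maximum(mu, 1e-300))
        return -ll.sum()

    rng = np.random.default_rng(seed)
    base = np.zeros(p_scale + has_shape)
    base[0] = np.log(max(np.std(d), 1.0))
    best = None
    for start in range(n_starts):
        x0 = base + (rng.normal(scale=0.4, size=base.size) if start else 0.0)
        res = optimize.minimize(negloglik, x0, method="L-BFGS-B")
        if best is None or (res.success and res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"detection fit failed to converge: {best}")

    # observed-information covariance by central finite differences
    vcov = None
    try:
        h = 1e-4
        k = best.x.size
        H = np.empty((k, k))
        for a in range(k):
            for b in range(a, k):
                ea, eb = np.eye(k)[a] * h, np.eye(k)[b] * h
                H[a, b] = H[b, a] = (
                    negloglik(best.x + ea + eb)
                    - negloglik(best.x + ea - eb)
                    - negloglik(best.x - ea + eb)
                    + negloglik(best.x - ea - eb)
                ) / (4 * h * h)
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        pass

    loglik = -float(best.fun)
    n_par = p_scale + has_shape
    levels = {}
    if covariates is not None:
        for col in covariates.columns:
            levels[col] = sorted(pd.unique(covariates[col]))
    return DetectionFunction(
        key=key,
        scale_coefficients=best.x[:p_scale],
        coef_names=names,
        truncation_w=float(w),
        loglik=loglik,
        aic=2.0 * n_par - 2.0 * loglik,
        n_obs=n,
        shape=(1.0 + np.exp(best.x[-1])) if has_shape else None,
        covariate_levels=levels,
        vcov=vcov,
    )


def fit_candidate_set(
    distances,
    covariates: pd.DataFrame,
    w: float,
    keys=("half_normal", "hazard_rate"),
    covariate_sets=((), ("bss",), ("sightability",), ("bss", "sightability")),
    seed: int = 0,
) -> list[DetectionFunction]:
    """The standard candidate ladder: each key with each covariate subset."""
    fits = []
    for key in keys:
        for cset in covariate_sets:
            cdf = covariates[list(cset)] if cset else None
            fits.append(
                fit_detection(distances, key=key, covariates=cdf, w=w, seed=seed)
            )
    return fits


def select_by_aic(fits: list[DetectionFunction]):
    """Minimum-AIC candidate among fits to the same data and truncation.

    Ties go to the model with fewest parameters.  Returns the winner and
    the full AIC table.
    """
    if not fits:
        raise ValueError("no candidate fits")
    n0, w0 = fits[0].n_obs, fits[0].truncation_w
    for f in fits[1:]:
        if f.n_obs != n0 or f.truncation_w != w0:
            raise ValueError(
                "candidates were fit to different data or truncation"
            )
    table = pd.DataFrame(
        {
            "key": [f.key for f in fits],
            "covariates": [
                "+".join(f.covariate_levels) or "none" for f in fits
            ],
            "n_params": [f.n_params for f in fits],
            "loglik": [f.loglik for f in fits],
            "aic": [f.aic for f in fits],
        }
    ).sort_values(["aic", "n_params"], kind="stable")
    table["delta_aic"] = table["aic"] - table["aic"].min()
    best_idx = min(
        range(len(fits)), key=lambda i: (round(fits[i].aic, 9), fits[i].n_params)
    )
    return fits[best_idx], table.reset_index(drop=True)


def gof_qq(
    df: DetectionFunction,
    distances,
    covariates: pd.DataFrame | None = None,
):
    """Kolmogorov-Smirnov goodness of fit of the fitted detection function.

    Each distance is transformed by its own fitted CDF (probability
    integral transform, handling per-observation covariates), then tested
    against uniformity.  Returns (statistic, p-value, sorted PIT values for
    a QQ plot).
    """
    d = np.asarray(distances, dtype=float)
    d = d[np.isfinite(d)]
    d = d[d <= df.truncation_w]
    if d.size == 0:
        raise ValueError("no distances inside truncation")
    if covariates is None or not df.covariate_levels:
        u = df.cdf(d)
    else:
        covariates = covariates.reset_index(drop=True)
        u = np.empty(d.size)
        for i, xi in enumerate(d):
            u[i] = float(df.cdf(xi, covariates.iloc[i].to_dict()))
    ks = stats.kstest(u, "uniform")
    return float(ks.statistic), float(ks.pvalue), np.sort(u)
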