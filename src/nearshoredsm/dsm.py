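"""Density surface model: penalized-spline quasi-Poisson GAM.

The spatial stage of the two-stage density surface model.  Whale counts per
survey segment are regressed on habitat covariates through a generalized
additive model with a quasi-Poisson family and log link, using the log
effective area ``log(2 x ESW x length)`` as an offset so the linear
predictor is log density (whales per km^2).

Smooth terms use cubic regression splines (values-at-knots
parameterization, quantile-placed knots, second-derivative penalty) with a
sum-to-zero identifiability constraint; the upwelling interaction is a
tensor product of two marginal splines with a roughness penalty in each
direction.  Smoothing parameters are selected by maximizing the restricted
maximum likelihood (REML) criterion of the Gaussian working model, with a
double-penalty shrinkage term on each smooth's penalty null space so that
uninformative covariates can be shrunk to ~0 effective degrees of freedom
(variable selection).  Dispersion is estimated from the Pearson statistic;
term p-values are Wald tests on smooth coefficient blocks with an
EDF-based reference rank.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

# ---------------------------------------------------------------------------
# cubic regression spline machinery


def _crs_matrices(knots: np.ndarray):
    """Natural-cubic-spline helper matrices for values-at-knots coefficients.

    Returns ``F`` mapping knot values to interior second derivatives and the
    second-derivative penalty ``S = D' B^-1 D``.
    """
    k = knots.size
    h = np.diff(knots)
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i < k - 3:
            B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
    F = linalg.solve(B, D, assume_a="pos")
    S = D.T @ F
    return F, (S + S.T) / 2.0


def _crs_eval(x: np.ndarray, knots: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Design matrix of the CRS basis at points x (linear extrapolation)."""
    x = np.asarray(x, dtype=float)
    k = knots.size
    Ffull = np.vstack([np.zeros(k), F, np.zeros(k)])  # 2nd derivs incl. ends
    X = np.zeros((x.size, k))
    j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, k - 2)
    inside = (x >= knots[0]) & (x <= knots[-1])
    idx = np.flatnonzero(inside)
    jj = j[idx]
    h = knots[jj + 1] - knots[jj]
    tm = knots[jj + 1] - x[idx]
    tp = x[idx] - knots[jj]
    am, ap = tm / h, tp / h
    cm = (tm**3 / h - h * tm) / 6.0
    cp = (tp**3 / h - h * tp) / 6.0
    X[idx, jj] += am
    X[idx, jj + 1] += ap
    X[idx] += cm[:, None] * Ffull[jj] + cp[:, None] * Ffull[jj + 1]
    # linear extrapolation beyond the boundary knots
    left = np.flatnonzero(x < knots[0])
    if left.size:
        h0 = knots[1] - knots[0]
        slope = -Ffull[1] * h0 / 6.0
        slope = slope.copy()
        slope[0] += -1.0 / h0
        slope[1] += 1.0 / h0
        X[left, 0] = 1.0
        X[left] += (x[left] - knots[0])[:, None] * slope
    right = np.flatnonzero(x > knots[-1])
    if right.size:
        h1 = knots[-1] - knots[-2]
        slope = Ffull[-2] * h1 / 6.0
        slope = slope.copy()
        slope[-2] += -1.0 / h1
        slope[-1] += 1.0 / h1
        X[right, -1] = 1.0
        X[right] += (x[right] - knots[-1])[:, None] * slope
    return X


def _quantile_knots(x: np.ndarray, k: int) -> np.ndarray:
    knots = np.unique(np.quantile(x, np.linspace(0.0, 1.0, k)))
    if knots.size < k:
        raise ValueError(
            f"need at least {k} distinct covariate values, found {knots.size}"
        )
    return knots


def build_smooth_basis(x, k: int = 5):
    """Cubic regression-spline basis with quantile knots and its penalty.

    Returns ``(X, S, knots, F)`` before any identifiability constraint: the
    design matrix over ``x``, the second-derivative penalty (null space =
    straight lines), the knots and the second-derivative map.
    """
    if k < 3:
        raise ValueError("k must be at least 3")
    x = np.asarray(x, dtype=float)
    knots = _quantile_knots(x, k)
    F, S = _crs_matrices(knots)
    return _crs_eval(x, knots, F), S, knots, F


def build_interaction_basis(x1, x2, k_marginal: int = 4):
    """Tensor-product basis of two marginal CRS bases, with both penalties.

    Returns ``(X, [S1, S2], (knots1, F1), (knots2, F2))``; the penalties act
    along each margin (``S1 (x) I`` and ``I (x) S2``) before constraint.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    kn1 = _quantile_knots(x1, k_marginal)
    kn2 = _quantile_knots(x2, k_marginal)
    F1, S1m = _crs_matrices(kn1)
    F2, S2m = _crs_matrices(kn2)
    X1 = _crs_eval(x1, kn1, F1)
    X2 = _crs_eval(x2, kn2, F2)
    X = np.einsum("ni,nj->nij", X1, X2).reshape(len(x1), -1)
    S1 = np.kron(S1m, np.eye(k_marginal))
    S2 = np.kron(np.eye(k_marginal), S2m)
    return X, [S1, S2], (kn1, F1), (kn2, F2)


def _constrain(X: np.ndarray, penalties: list[np.ndarray]):
    """Apply the sum-to-zero constraint over the training rows.

    Reparameterizes to the null space of ``1'X``, dropping one dimension;
    returns the constrained design, penalties and the basis ``Z``.
    """
    C = X.sum(axis=0, keepdims=True)
    Z = linalg.null_space(C)
    return X @ Z, [Z.T @ S @ Z for S in penalties], Z


def _null_space_penalty(penalties: list[np.ndarray], tol: float = 1e-9):
    """Projection onto the joint null space of a term's penalties."""
    S = sum(penalties)
    vals, vecs = linalg.eigh(S)
    null = vecs[:, vals < tol * max(vals.max(), 1.0)]
    if null.shape[1] == 0:
        return None
    return null @ null.T


def _scale_penalty(S: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(S, 2)
    return S / nrm if nrm > 0 else S


# ---------------------------------------------------------------------------
# model configuration and fit container

DEFAULT_SMOOTHS = ("depth", "dist_coast", "shelf_width", "dist_estuary", "sst")


@dataclass
class DsmConfig:
    """Configuration of one region's density surface model."""

    region: int = 1
    smooth_terms: dict = None          # name -> k (basis dimension)
    interaction: tuple = ("cum_cuti", "cum_relax")
    interaction_k: int = 15            # total tensor dimension before constraint - 1
    parametric_terms: tuple = ("substrate",)
    include_dist_cape: bool = None     # default: not in region 1
    shrinkage: bool = True

    def __post_init__(self):
        if self.smooth_terms is None:
            self.smooth_terms = {name: 5 for name in DEFAULT_SMOOTHS}
        if self.include_dist_cape is None:
            self.include_dist_cape = self.region != 1
        if self.include_dist_cape and "dist_cape" not in self.smooth_terms:
            self.smooth_terms = {**self.smooth_terms, "dist_cape": 5}
        if not self.include_dist_cape:
            self.smooth_terms.pop("dist_cape", None)
        for name, k in self.smooth_terms.items():
            if k < 3:
                raise ValueError(f"k for {name} must be >= 3")
        if self.interaction is not None and self.interaction_k < max(
            self.smooth_terms.values(), default=3
        ):
            raise ValueError("interaction k must be >= marginal smooth k")

    @property
    def interaction_k_marginal(self) -> int:
        # tensor dimension k_m^2 loses 1 to the constraint; k_m = 4 gives 15
        return int(round(np.sqrt(self.interaction_k + 1)))

    def to_yaml(self, path) -> None:
        import yaml

        payload = {
            "region": self.region,
            "smooth_terms": dict(self.smooth_terms),
            "interaction": list(self.interaction) if self.interaction else None,
            "interaction_k": self.interaction_k,
            "parametric_terms": list(self.parametric_terms),
            "include_dist_cape": self.include_dist_cape,
            "shrinkage": self.shrinkage,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "DsmConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if payload.get("interaction") is not None:
            payload["interaction"] = tuple(payload["interaction"])
        if "parametric_terms" in payload:
            payload["parametric_terms"] = tuple(payload["parametric_terms"])
        return cls(**payload)


@dataclass
class _Term:
    name: str
    covariates: tuple
    cols: slice
    knots: list          # list of (knots, F) per margin
    Z: np.ndarray
    penalty_ids: list    # indices into the global penalty list


@dataclass
class DsmFit:
    """A fitted density surface model for one region."""

    config: DsmConfig
    coef: np.ndarray
    vcov: np.ndarray             # Bayesian covariance, phi * (X'WX + S)^-1
    dispersion: float
    edf: dict                    # per-term effective degrees of freedom
    edf_total: float
    lambdas: np.ndarray
    null_deviance: float
    deviance: float
    term_pvalues: dict
    n_obs: int
    offset_col: str
    terms: list = field(default_factory=list, repr=False)
    parametric_info: dict = field(default_factory=dict, repr=False)
    training_ranges: dict = field(default_factory=dict, repr=False)
    training_dynamic: pd.DataFrame = None  # reference covariates for ExDet

    @property
    def deviance_explained(self) -> float:
        """Percent deviance explained, 100 (D_null - D_resid) / D_null."""
        if self.null_deviance <= 0:
            return 0.0
        return 100.0 * (self.null_deviance - self.deviance) / self.null_deviance

    # -- prediction -------------------------------------------------------

    def _model_matrix(self, data: pd.DataFrame) -> np.ndarray:
        n = len(data)
        ncol = self.vcov.shape[0]
        X = np.zeros((n, ncol))
        X[:, 0] = 1.0
        for name, info in self.parametric_info.items():
            col, level, j = info["column"], info["level"], info["index"]
            X[:, j] = (data[col].astype(str) == level).to_numpy(dtype=float)
        for term in self.terms:
            mats = []
            for (kn, F), covname in zip(term.knots, term.covariates):
                mats.append(_crs_eval(data[covname].to_numpy(dtype=float),
                                      np.asarray(kn), np.asarray(F)))
            if len(mats) == 1:
                Xt = mats[0]
            else:
                Xt = np.einsum("ni,nj->nij", mats[0], mats[1]).reshape(n, -1)
            X[:, term.cols] = Xt @ term.Z
        return X

    def predict(self, data: pd.DataFrame, offset=None, se: bool = False):
        """Linear predictor (plus offset) and optionally its standard error."""
        X = self._model_matrix(data)
        eta = X @ self.coef
        if offset is not None:
            eta = eta + np.asarray(offset, dtype=float)
        if not se:
            return eta
        se_fit = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.vcov, X), 0.0))
        return eta, se_fit

    def predict_response(self, data: pd.DataFrame, offset=None):
        """Expected count (or abundance when offset = log area)."""
        return np.exp(self.predict(data, offset=offset))

    def sample_coefficients(self, size: int, rng) -> np.ndarray:
        """Draws from the approximate posterior N(coef, vcov)."""
        return rng.multivariate_normal(self.coef, self.vcov, size=size,
                                       method="eigh")

    # -- persistence ------------------------------------------------------

    def to_json(self, path) -> None:
        def arr(a):
            return np.asarray(a).tolist()
        payload = {
            "coef": arr(self.coef),
            "vcov": arr(self.vcov),
            "dispersion": self.dispersion,
            "edf": self.edf,
            "edf_total": self.edf_total,
            "lambdas": arr(self.lambdas),
            "null_deviance": self.null_deviance,
            "deviance": self.deviance,
            "term_pvalues": self.term_pvalues,
            "n_obs": self.n_obs,
            "offset_col": self.offset_col,
            "training_ranges": {k: arr(v) for k, v in self.training_ranges.items()},
            "parametric_info": self.parametric_info,
            "terms": [
                {
                    "name": t.name,
                    "covariates": list(t.covariates),
                    "cols": [t.cols.start, t.cols.stop],
                    "knots": [[arr(kn), arr(F)] for kn, F in t.knots],
                    "Z": arr(t.Z),
                }
                for t in self.terms
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


# ---------------------------------------------------------------------------
# offsets


def build_offset(esw_km, length_km) -> np.ndarray:
    """Log effective area of a segment: log(2 x ESW x length), km^2.

    The strip is two-sided, hence the factor 2.
    """
    esw_km = np.asarray(esw_km, dtype=float)
    length_km = np.asarray(length_km, dtype=float)
    if np.any(esw_km <= 0) or np.any(length_km <= 0):
        raise ValueError("ESW and segment length must be positive")
    return np.log(2.0 * esw_km * length_km)


# ---------------------------------------------------------------------------
# fitting


def _pirls(y, X, offset, penalties, lam, max_iter=60, tol=1e-9):
    """Penalized IRLS for the log-link quasi-Poisson working model."""
    P = sum(l * S for l, S in zip(lam, penalties))
    eta = np.log(y + 0.5)
    dev_old = np.inf
    beta = None
    for _ in range(max_iter):
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        z = (eta - offset) + (y - mu) / mu
        W = mu
        XtW = X.T * W
        A = XtW @ X + P
        try:
            beta = linalg.solve(A, XtW @ z, assume_a="pos")
        except linalg.LinAlgError as exc:
            raise RuntimeError(f"PIRLS linear solve failed: {exc}") from exc
        eta = np.clip(X @ beta + offset, -30.0, 30.0)
        mu = np.exp(eta)
        dev = _poisson_deviance(y, mu)
        if not np.isfinite(dev):
            raise RuntimeError("PIRLS diverged (non-finite deviance)")
        if abs(dev - dev_old) < tol * (abs(dev) + 0.1):
            break
        dev_old = dev
    return beta, eta, mu, W, z, A


def _poisson_deviance(y, mu) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(t - (y - mu)))


def _logdet_penalty(penalties, term_penalty_ids, lam) -> float:
    """Log pseudo-determinant of the total penalty, block by term."""
    out = 0.0
    for ids, block in term_penalty_ids:
        Sb = sum(lam[i] * penalties[i][np.ix_(block, block)] for i in ids)
        vals = linalg.eigvalsh(Sb)
        pos = vals[vals > 1e-10 * max(vals.max(), 1.0)]
        out += float(np.sum(np.log(pos)))
    return out


def _working_reml(XtWX, XtWz, ztWz, n, penalties, term_penalty_ids, lam,
                  n_unpenalized):
    """Profiled Gaussian REML of the fixed working model for one lambda.

    The working response and weights are held fixed (performance
    iteration), so the residual sum is comparable across smoothing
    parameters; the score is minimized in the smoothing loop.
    """
    P = sum(l * S for l, S in zip(lam, penalties))
    A = XtWX + P
    try:
        c, low = linalg.cho_factor(A)
    except linalg.LinAlgError:
        return np.inf, None
    beta = linalg.cho_solve((c, low), XtWz)
    # rss_p = z'Wz - 2 b'X'Wz + b'(X'WX)b + b'Pb = z'Wz - b'X'Wz (at optimum)
    rss_p = float(ztWz - beta @ XtWz)
    if rss_p <= 0:
        return np.inf, None
    logdet_A = 2.0 * float(np.sum(np.log(np.diag(c))))
    logdet_S = _logdet_penalty(penalties, term_penalty_ids, lam)
    score = (n - n_unpenalized) * np.log(rss_p) + logdet_A - logdet_S
    return score, beta


def fit_dsm(
    data: pd.DataFrame,
    config: DsmConfig,
    offset_col: str = "offset",
    response_col: str = "n_whales",
    lambda_bounds: tuple = (-7.0, 16.0),
    n_sweeps: int = 3,
    xatol: float = 0.15,
) -> DsmFit:
    """Fit the region's density surface model.

    ``data`` must contain the response, the log-effective-area offset and
    every covariate named in ``config``; rows with missing values are
    dropped.  Smoothing parameters (one per penalty, two per shrinkage
    smooth) are optimized by cyclic Brent search on the log scale against
    the working-model REML criterion.
    """
    cols = (
        [response_col, offset_col]
        + list(config.smooth_terms)
        + (list(config.interaction) if config.interaction else [])
        + list(config.parametric_terms)
    )
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise ValueError(f"data lacks columns {missing_cols}")
    df = data[cols].dropna().reset_index(drop=True)
    n = len(df)
    y = df[response_col].to_numpy(dtype=float)
    offset = df[offset_col].to_numpy(dtype=float)

    blocks = [np.ones((n, 1))]
    col_names = ["(Intercept)"]
    parametric_info = {}
    for pcol in config.parametric_terms:
        levels = sorted(df[pcol].astype(str).unique())
        for lev in levels[1:]:
            parametric_info[f"{pcol}[{lev}]"] = {
                "column": pcol, "level": lev, "index": len(col_names),
            }
            blocks.append(
                (df[pcol].astype(str) == lev).to_numpy(dtype=float)[:, None]
            )
            col_names.append(f"{pcol}[{lev}]")
    n_unpenalized = len(col_names)

    penalties_local = []   # (term_index, [S...]) in term-local coordinates
    terms: list[_Term] = []
    start = len(col_names)
    for name, k in config.smooth_terms.items():
        Xt, S, knots, F = build_smooth_basis(df[name].to_numpy(dtype=float), k)
        Xc, Ss, Z = _constrain(Xt, [S])
        Ss = [_scale_penalty(Ss[0])]
        if config.shrinkage:
            S0 = _null_space_penalty(Ss)
            if S0 is not None:
                Ss.append(S0)
        terms.append(_Term(name=f"s({name})", covariates=(name,),
                           cols=slice(start, start + Xc.shape[1]),
                           knots=[(knots, F)], Z=Z, penalty_ids=[]))
        penalties_local.append(Ss)
        blocks.append(Xc)
        start += Xc.shape[1]
    if config.interaction is not None:
        c1, c2 = config.interaction
        km = config.interaction_k_marginal
        Xt, Ss, m1, m2 = build_interaction_basis(
            df[c1].to_numpy(dtype=float), df[c2].to_numpy(dtype=float), km
        )
        Xc, Ss, Z = _constrain(Xt, Ss)
        Ss = [_scale_penalty(S) for S in Ss]
        if config.shrinkage:
            S0 = _null_space_penalty(Ss)
            if S0 is not None:
                Ss.append(S0)
        terms.append(_Term(name=f"te({c1},{c2})", covariates=(c1, c2),
                           cols=slice(start, start + Xc.shape[1]),
                           knots=[m1, m2], Z=Z, penalty_ids=[]))
        penalties_local.append(Ss)
        blocks.append(Xc)
        start += Xc.shape[1]

    X = np.hstack(blocks)
    ncol = X.shape[1]
    if n < 10 * ncol:
        import warnings

        warnings.warn(
            f"only {n} observations for {ncol} coefficients; "
            "fit may be unstable", stacklevel=2
        )

    # embed term-local penalties in the full coefficient space
    penalties = []
    term_penalty_ids = []
    for term, Ss in zip(terms, penalties_local):
        ids = []
        block = np.arange(term.cols.start, term.cols.stop)
        for S in Ss:
            P = np.zeros((ncol, ncol))
            P[np.ix_(block, block)] = S
            ids.append(len(penalties))
            penalties.append(P)
        term.penalty_ids = ids
        term_penalty_ids.append((ids, block))

    nlam = len(penalties)
    rho = np.zeros(nlam)  # log lambdas

    # performance iteration: converge PIRLS at the current smoothing, then
    # optimize all log-lambdas by Gaussian REML of the *fixed* working
    # model (so residual sums are comparable across lambda), and repeat
    state = None
    for outer in range(8):
        beta, eta, mu, W, z, A = _pirls(y, X, offset, penalties, np.exp(rho))
        state = (beta, eta, mu, W, z, A)
        XtW = X.T * W
        XtWX = XtW @ X
        XtWz = XtW @ z
        ztWz = float(np.sum(W * z * z))
        n = y.size

        def score_at(rho_vec):
            s, _ = _working_reml(
                XtWX, XtWz, ztWz, n, penalties, term_penalty_ids,
                np.exp(rho_vec), n_unpenalized,
            )
            return s if np.isfinite(s) else 1e12

        best_score = score_at(rho)
        rho_old = rho.copy()
        for _ in range(n_sweeps):
            improved = False
            for j in range(nlam):
                def f(r, j=j):
                    trial = rho.copy()
                    trial[j] = r
                    return score_at(trial)

                res = optimize.minimize_scalar(
                    f, bounds=lambda_bounds, method="bounded",
                    options={"xatol": xatol},
                )
                if res.fun < best_score - 1e-8:
                    rho[j] = res.x
                    best_score = res.fun
                    improved = True
            if not improved:
                break
        if np.max(np.abs(rho - rho_old)) < 0.05:
            break
    beta, eta, mu, W, z, A = _pirls(y, X, offset, penalties, np.exp(rho))
    lam = np.exp(rho)

    Ainv = linalg.inv(A)
    XtWX = (X.T * W) @ X
    Fmat = Ainv @ XtWX
    edf_total = float(np.trace(Fmat))
    df_resid = max(n - edf_total, 1.0)
    pearson = float(np.sum((y - mu) ** 2 / mu))
    dispersion = pearson / df_resid
    vcov = dispersion * Ainv

    deviance = _poisson_deviance(y, mu)
    alpha = np.log(y.sum() / np.exp(offset).sum())
    null_dev = _poisson_deviance(y, np.exp(alpha + offset))

    edf = {}
    pvals = {}
    diagF = np.diag(Fmat)
    for term in terms:
        block = np.arange(term.cols.start, term.cols.stop)
        edf_t = float(diagF[block].sum())
        edf[term.name] = edf_t
        bj = beta[block]
        Vj = vcov[np.ix_(block, block)]
        r = int(max(1, min(round(edf_t), block.size)))
        vals, vecs = linalg.eigh(Vj)
        order = np.argsort(vals)[::-1][:r]
        good = vals[order] > 1e-12 * max(vals.max(), 1e-300)
        U = vecs[:, order[good]]
        lv = vals[order[good]]
        stat = float(np.sum((U.T @ bj) ** 2 / lv))
        pvals[term.name] = float(stats.f.sf(stat / r, r, df_resid))
    for name, info in parametric_info.items():
        j = info["index"]
        tstat = beta[j] / np.sqrt(vcov[j, j])
        pvals[name] = float(2.0 * stats.t.sf(abs(tstat), df_resid))

    dyn_cols = [c for c in ("sst", "cum_cuti", "cum_relax") if c in df.columns]
    ranges = {c: (float(df[c].min()), float(df[c].max()))
              for c in config.smooth_terms}
    for c in dyn_cols:
        ranges[c] = (float(df[c].min()), float(df[c].max()))

    return DsmFit(
        config=config,
        coef=beta,
        vcov=vcov,
        dispersion=dispersion,
        edf=edf,
        edf_total=edf_total,
        lambdas=lam,
        null_deviance=null_dev,
        deviance=deviance,
        term_pvalues=pvals,
        n_obs=n,
        offset_col=offset_col,
        terms=terms,
        parametric_info=parametric_info,
        training_ranges=ranges,
        training_dynamic=df[dyn_cols].copy() if dyn_cols else None,
    )


def deviance_explained(fit: DsmFit) -> float:
    """Percent of null deviance explained by the fitted model."""
    return fit.deviance_explained


def partial_response(fit: DsmFit, term_name: str, grid) -> pd.DataFrame:
    """A term's centred contribution to the linear predictor over a grid.

    ``grid`` is an array for 1-D smooths or an (m, 2) array for the tensor
    interaction.  Returns the fitted partial effect with pointwise +-2 SE
    intervals from the coefficient covariance.
    """
    term = next((t for t in fit.terms if t.name == term_name), None)
    if term is None:
        raise ValueError(
            f"term {term_name!r} not in model "
            f"(has {[t.name for t in fit.terms]})"
        )
    grid = np.asarray(grid, dtype=float)
    if len(term.covariates) == 1:
        g = grid.reshape(-1, 1)
    else:
        g = grid.reshape(-1, 2)
    mats = []
    for (kn, F), col in zip(term.knots, range(g.shape[1])):
        mats.append(_crs_eval(g[:, col], np.asarray(kn), np.asarray(F)))
    Xt = (
        mats[0]
        if len(mats) == 1
        else np.einsum("ni,nj->nij", mats[0], mats[1]).reshape(len(g), -1)
    )
    Xc = Xt @ term.Z
    block = np.arange(term.cols.start, term.cols.stop)
    eff = Xc @ fit.coef[block]
    V = fit.vcov[np.ix_(block, block)]
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xc, V, Xc), 0.0))
    out = {"effect": eff, "se": se, "lo": eff - 2 * se, "hi": eff + 2 * se}
    if len(term.covariates) == 1:
        out[term.covariates[0]] = g[:, 0]
    else:
        out[term.covariates[0]] = g[:, 0]
        out[term.covariates[1]] = g[:, 1]
    return pd.DataFrame(out)


def observed_support_mask(
    fit: DsmFit, term_name: str, grid, radius_quantile: float = 0.95
) -> np.ndarray:
    """True where an interaction grid point is near observed training data.

    Points farther (in standardized coordinates) from every training
    observation than the ``radius_quantile`` of nearest-neighbour training
    distances are masked out — conditions that did not occur in the data.
    """
    term = next(t for t in fit.terms if t.name == term_name)
    if fit.training_dynamic is None:
        raise ValueError("no training covariates stored")
    cols = list(term.covariates)
    train = fit.training_dynamic[cols].to_numpy(dtype=float)
    scale = train.std(axis=0)
    scale[scale == 0] = 1.0
    t = train / scale
    g = np.asarray(grid, dtype=float).reshape(-1, len(cols)) / scale
    from scipy.spatial import cKDTree

    t = np.unique(t, axis=0)  # repeated (date, lat-bin) values collapse
    tree = cKDTree(t)
    if len(t) > 1:
        d_self, _ = tree.query(t, k=2)
        nn = d_self[:, 1]
        nn = nn[nn > 0]
        r = 2.0 * (np.quantile(nn, radius_quantile) if nn.size else 0.0)
    else:
        r = 0.0
    r = max(r, 0.05 * np.sqrt(t.shape[1]))  # floor: 5% of the scaled range
    d_grid, _ = tree.query(g, k=1)
    return d_grid <= r
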