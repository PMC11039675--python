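import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from nearshoredsm import dsm


# ---------------------------------------------------------------------------
# offset


def test_build_offset_arithmetic():
    assert dsm.build_offset(0.25, 5.0) == pytest.approx(np.log(2.5))
    # doubling ESW adds log 2
    assert dsm.build_offset(0.5, 5.0) - dsm.build_offset(0.25, 5.0) == (
        pytest.approx(np.log(2.0))
    )
    with pytest.raises(ValueError):
        dsm.build_offset(0.25, 0.0)
    with pytest.raises(ValueError):
        dsm.build_offset(-0.1, 5.0)


# ---------------------------------------------------------------------------
# spline basis


def test_penalty_null_space_is_linear():
    x = np.linspace(0, 10, 200)
    X, S, knots, F = dsm.build_smooth_basis(x, k=5)
    beta_line = 2.0 + 3.0 * knots  # values-at-knots of a straight line
    assert beta_line @ S @ beta_line == pytest.approx(0.0, abs=1e-9)
    beta_curve = knots**2
    assert beta_curve @ S @ beta_curve > 1e-6


def test_basis_interpolates_knot_values():
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 10, 300)
    X, S, knots, F = dsm.build_smooth_basis(x, k=6)
    beta = rng.normal(size=6)
    Xk = dsm._crs_eval(knots, knots, F)
    np.testing.assert_allclose(Xk @ beta, beta, atol=1e-10)


def test_basis_requires_distinct_values():
    with pytest.raises(ValueError):
        dsm.build_smooth_basis(np.ones(50), k=5)
    with pytest.raises(ValueError):
        dsm.build_smooth_basis(np.linspace(0, 1, 50), k=2)


def test_constraint_centers_columns():
    x = np.linspace(0, 5, 100)
    X, S, *_ = dsm.build_smooth_basis(x, k=5)
    Xc, Ss, Z = dsm._constrain(X, [S])
    np.testing.assert_allclose(Xc.sum(axis=0), 0.0, atol=1e-8)
    assert Xc.shape[1] == 4


def test_interaction_basis_dimensions():
    rng = np.random.default_rng(1)
    x1, x2 = rng.uniform(0, 1, 200), rng.uniform(0, 1, 200)
    X, Ss, m1, m2 = dsm.build_interaction_basis(x1, x2, k_marginal=4)
    assert X.shape == (200, 16)
    assert len(Ss) == 2
    # both penalties annihilate the constant surface
    const = np.ones(16) / 4
    for S in Ss:
        assert const @ S @ const == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# fitting behaviour on constructed data


def _poisson_frame(n=800, seed=0, truth=lambda x: 0.5 * np.sin(2 * x)):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 3, n)
    z = rng.uniform(0, 1, n)
    offset = np.log(rng.uniform(1.0, 3.0, n))
    eta = 0.3 + truth(x) + offset
    y = rng.poisson(np.exp(eta))
    return pd.DataFrame(
        {"n_whales": y, "x": x, "z": z, "offset": offset,
         "substrate": np.where(rng.random(n) < 0.5, "hard", "soft")}
    )


def simple_config(**kw):
    base = dict(
        region=1,
        smooth_terms={"x": 5, "z": 5},
        interaction=None,
        parametric_terms=(),
        include_dist_cape=False,
    )
    base.update(kw)
    return dsm.DsmConfig(**base)


def test_fit_recovers_smooth_and_shrinks_noise():
    df = _poisson_frame(n=1200, seed=3)
    fit = dsm.fit_dsm(df, simple_config())
    # noise covariate z shrinks away; real term keeps flexibility
    assert fit.edf["s(z)"] < 1.0
    assert fit.edf["s(x)"] > 1.5
    grid = np.linspace(0.2, 2.8, 25)
    pr = dsm.partial_response(fit, "s(x)", grid)
    truth_centered = 0.5 * np.sin(2 * grid) - np.mean(0.5 * np.sin(2 * df["x"]))
    frac = np.mean((truth_centered >= pr["lo"]) & (truth_centered <= pr["hi"]))
    assert frac >= 0.9


def test_offset_identity_shifts_intercept_only():
    """Scaling every effective area by c moves only the intercept by -log c."""
    df = _poisson_frame(n=700, seed=5)
    fit1 = dsm.fit_dsm(df, simple_config())
    df2 = df.copy()
    df2["offset"] = df2["offset"] + np.log(3.0)
    fit2 = dsm.fit_dsm(df2, simple_config())
    assert fit2.coef[0] - fit1.coef[0] == pytest.approx(-np.log(3.0), abs=1e-4)
    np.testing.assert_allclose(fit2.coef[1:], fit1.coef[1:], atol=1e-4)


def test_fitted_means_positive_and_residuals_centered(fitted_dsm, small_survey):
    _, seg, _ = small_survey
    fit = fitted_dsm
    segc = seg.dropna(
        subset=list(fit.config.smooth_terms) + list(fit.config.interaction)
    )
    mu = fit.predict_response(segc, offset=segc["offset"])
    assert (mu > 0).all()
    pearson = (segc["n_whales"] - mu) / np.sqrt(mu)
    assert abs(pearson.mean()) < 0.05


def test_intercept_only_truth_explains_almost_nothing():
    rng = np.random.default_rng(11)
    n = 1000
    df = pd.DataFrame(
        {
            "n_whales": rng.poisson(1.2, n),
            "x": rng.uniform(0, 1, n),
            "z": rng.uniform(0, 1, n),
            "offset": np.zeros(n),
        }
    )
    fit = dsm.fit_dsm(df, simple_config())
    assert fit.deviance_explained < 2.0


def test_deviance_explained_in_range(fitted_dsm):
    assert 0.0 <= fitted_dsm.deviance_explained <= 100.0
    assert fitted_dsm.dispersion > 0
    for name, e in fitted_dsm.edf.items():
        k = 15 if name.startswith("te(") else 5
        assert e <= k - 1 + 1e-6


def test_partial_response_centered_and_errors(fitted_dsm, small_survey):
    _, seg, _ = small_survey
    fit = fitted_dsm
    with pytest.raises(ValueError):
        dsm.partial_response(fit, "s(not_a_term)", np.linspace(0, 1, 5))
    x = seg["dist_coast"].dropna().to_numpy()
    pr = dsm.partial_response(fit, "s(dist_coast)", x)
    # sum-to-zero constraint: effect has mean ~0 over training values
    assert abs(pr["effect"].mean()) < 0.05


def test_interaction_support_mask(fitted_dsm, small_survey):
    _, seg, _ = small_survey
    fit = fitted_dsm
    cc = np.linspace(seg["cum_cuti"].min(), seg["cum_cuti"].max(), 8)
    cr = np.linspace(seg["cum_relax"].min(), seg["cum_relax"].max(), 8)
    gg = np.array([[a, b] for a in cc for b in cr])
    mask = dsm.observed_support_mask(fit, "te(cum_cuti,cum_relax)", gg)
    assert mask.dtype == bool and 0 < mask.sum() < len(gg)
    # a far-away point is always masked out
    far = np.array([[seg["cum_cuti"].max() * 10, seg["cum_relax"].max() * 10]])
    assert not dsm.observed_support_mask(fit, "te(cum_cuti,cum_relax)", far)[0]


def test_fit_reports_missing_columns():
    df = _poisson_frame(100)
    with pytest.raises(ValueError, match="lacks columns"):
        dsm.fit_dsm(df.drop(columns=["z"]), simple_config())


def test_config_yaml_round_trip(tmp_path):
    cfg = dsm.DsmConfig(region=2)
    path = tmp_path / "dsm.yaml"
    cfg.to_yaml(path)
    back = dsm.DsmConfig.from_yaml(path)
    assert back.region == 2
    assert back.include_dist_cape  # region 2 keeps distance-to-cape
    assert back.smooth_terms == cfg.smooth_terms
    assert back.interaction == ("cum_cuti", "cum_relax")


def test_model_json_round_trippable(tmp_path, fitted_dsm):
    path = tmp_path / "fit.json"
    fitted_dsm.to_json(path)
    import json

    payload = json.loads(path.read_text())
    assert len(payload["coef"]) == len(fitted_dsm.coef)
    assert payload["n_obs"] == fitted_dsm.n_obs


# ---------------------------------------------------------------------------
# independent cross-check against mgcv


def test_agrees_with_mgcv_reference(tmp_path):
    """Same data, same model family: fits should closely agree with mgcv.

    mgcv is the standard implementation of REML-penalized GAMs; on a simple
    one-smooth quasi-Poisson model the two fits should produce nearly
    identical fitted values and deviance explained.
    """
    df = _poisson_frame(n=600, seed=21)
    cfg = dsm.DsmConfig(
        region=1, smooth_terms={"x": 5}, interaction=None,
        parametric_terms=(), include_dist_cape=False,
    )
    fit = dsm.fit_dsm(df, cfg)
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    rfile = tmp_path / "ref.R"
    rfile.write_text(
        textwrap.dedent(
            f"""
            d <- read.csv("{csv}")
            library(mgcv)
            m <- gam(n_whales ~ s(x, k=5, bs="cr") + offset(offset),
                     family=quasipoisson(), method="REML", data=d)
            dev <- 100 * (1 - deviance(m) / m$null.deviance)
            writeLines(c(as.character(dev), as.character(summary(m)$dispersion)))
            write.csv(data.frame(mu=fitted(m)), "{tmp_path}/mu.csv", row.names=FALSE)
            """
        )
    )
    try:
        subprocess.run(
            ["Rscript", "--vanilla", str(rfile)], check=True,
            capture_output=True, timeout=120,
        )
    except (FileNotFoundError, subprocess.CalledProcessError) as exc:
        pytest.skip(f"mgcv reference unavailable: {exc}")
    lines = (tmp_path / "mu.csv").read_text().splitlines()
    mu_ref = np.array([float(v) for v in lines[1:]])
    segc = df.dropna()
    mu = fit.predict_response(segc, offset=segc["offset"])
    corr = np.corrcoef(mu, mu_ref)[0, 1]
    assert corr > 0.99
    assert np.abs(mu - mu_ref).mean() / mu_ref.mean() < 0.05
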