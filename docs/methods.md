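# Methods

This note documents the models implemented in `nearshoredsm`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## The two-stage density surface model

The package implements the standard two-stage line-transect density
surface model (DSM) for a nearshore whale survey.

**Stage 1 — detection.** Perpendicular sighting distances x are modelled
with a truncated detection function g(x), either half-normal
g(x) = exp(−x²/2σ²) or hazard-rate g(x) = 1 − exp(−(x/σ)^−b), with the
scale entering through a log-linear predictor in observation-condition
covariates (Beaufort sea state, sightability):
log σ(z) = β₀ + Σ β_level. Each observation contributes
g(x; σ(z)) / ∫₀ʷ g(u; σ(z)) du to the likelihood, where the truncation w
is the 98th percentile of observed distances (optionally rounded to a
stated figure such as 1000 m). Availability at the surface is treated as
1: the survey platform is slow relative to whale surfacing intervals.
Candidates (each key × each covariate subset) are compared by AIC, with
ties going to the smaller model. The effective strip width is
ESW = ∫₀ʷ g(x; σ(z)) dx — closed form σ√(π/2)·erf(w/(σ√2)) for the
half-normal, adaptive quadrature for the hazard rate. The hazard-rate
shape is bounded below at 1 so the curve keeps a shoulder; the optimizer
is bounded quasi-Newton on log parameters with three starts.

Sightings whose distance was not recorded are excluded from detection
fitting but their group sizes still count toward segment totals. The
detection model is fitted to sightings (groups), not individuals, and the
ESW applies per sighting; whale counts enter only the spatial stage.
Segments in Beaufort ≥ 4 are removed before the spatial stage because no
ESW can be assigned there.

**Stage 2 — spatial model.** Whale counts per segment follow a
quasi-Poisson GAM with log link and offset log(2·ESW·L) (two-sided strip,
km²), so the linear predictor is log density in whales/km². Smooth terms
(k = 5) are cubic regression splines in the values-at-knots
parameterization with quantile-placed knots and the exact
second-derivative penalty S = D′B⁻¹D; beyond the boundary knots the
spline continues linearly. Each smooth carries a sum-to-zero constraint
applied by reparameterizing to the null space of the column-sum
functional. The upwelling interaction s(cumulative CUTI, cumulative
relaxation) is a tensor product of two marginal cubic splines (4 × 4 = 16
coefficients, 15 after the constraint) with one roughness penalty per
margin. Substrate (hard/soft) is a parametric two-level term. Distance to
cape is omitted in region 1, where no prominent capes exist.

Smoothing parameters are selected by restricted maximum likelihood via
performance iteration: penalized IRLS is run to convergence, the working
response and weights are frozen, all log-λ are optimized by cyclic Brent
search against the profiled Gaussian REML score

(n − M_p)·log RSS_p + log|X′WX + S_λ| − log|S_λ|₊,

and the loop repeats until the λ stabilize. Freezing the working model
inside the λ search matters: re-converging IRLS at every trial λ makes
the Pearson-scale residual sum non-comparable across λ (it can decrease
as the fit degrades) and systematically over-shrinks strong terms.

**Shrinkage.** Variable selection uses the double-penalty approach: each
smooth's penalty null space (the functions its roughness penalty cannot
touch — linear trends, and the bilinear sheet for the tensor term)
receives its own ridge penalty with its own REML-estimated λ, so a term
with no support in the data can be shrunk to ~0 effective degrees of
freedom. On identical data this reproduces mgcv's `select=TRUE` EDFs to
within a few percent. Its operating characteristics should be understood:
REML estimates each null-space variance from what amounts to a single
coefficient, so a truly inert covariate retains EDF > 0.5 in roughly a
quarter to a third of replicates at the survey scales used here — that is
a property of REML-based selection, not of this implementation.

Dispersion is the Pearson statistic over residual degrees of freedom
(n − total EDF). Term p-values are Wald statistics on each smooth's
coefficient block using the Bayesian covariance φ(X′WX+S)⁻¹ at rank
round(EDF), referred to an F distribution — the usual approximation when
the fitting software is not asked for anything fancier. Deviance
explained is 100·(D_null − D_resid)/D_null with the intercept+offset
null model (closed form: α̂ = log Σy − log Σe^offset).

## Habitat covariates

Eight covariates drive the density surface:

| covariate | definition | units |
| --- | --- | --- |
| depth | bathymetry at segment centroid | m |
| dist_coast | distance from centroid to coastline | km |
| shelf_width | coast → 200 m isobath, one value per latitude | km |
| dist_cape | signed distance to nearest prominent cape (− north, + south) | km |
| dist_estuary | distance to nearest river estuary > 300 ha | km |
| substrate | majority hard/soft over the segment footprint (tie → soft) | — |
| sst | sea-surface temperature, nearest grid latitude, exact date | °C |
| cum_cuti, cum_relax | cumulative upwelling and relaxation since spring transition | — , days |

Capes are detected by smoothing the coastline coordinates with a 200 km
centred moving average over along-shore arc length (windows shrink
symmetrically at the ends so the smoothed line is not dragged inland) and
labelling contiguous runs where the deviation exceeds 5 km; each run
collapses to its maximal-deviation point.

The upwelling indices come from the daily Coastal Upwelling Transport
Index (CUTI) per 1° latitude bin. A 10-day centred moving average (edges
by window shrinkage) removes spikes; note an even window spans one more
day before than after its centre, so a pure linear ramp shifts by half a
day's increment — the cost of matching the stated filter length. The
spring transition is the date of the minimum of the within-year running
cumulative sum of smoothed CUTI, the season end the date of its maximum;
all-positive or all-negative years are flagged degenerate. Cumulative
CUTI restarts at zero on the transition date and accumulates strictly
after it. The relaxation threshold is the mean smoothed CUTI over all
upwelling-season days pooled across every study year, one value per
latitude bin; a relaxation day is strictly below threshold (boundary
equality is not an event), and the smoothed series is used for both the
threshold and the event classification (a toggle for raw CUTI exists, the
definition being ambiguous between sources). Cumulative indices are
defined as 0 before the transition.

All geometry lives in a local equidistant plane (alongshore km,
cross-shore km; latitude = lat₀ + y/111.2) so distances are metric;
rasters are 1 km cells stored as plain-text ESRI ASCII grids, vector data
as GeoJSON.

## Prediction, extrapolation filtering, uncertainty

Predictions run on a 5 km grid clipped (true clipped areas, via
polygon intersection) to the band within 5 km of the coastline, daily
from 15 May to 30 August: N_cell = area·exp(η̂). ExDet screens each day's
grid against the model's training distribution of the *dynamic*
covariates only (SST, cumulative CUTI, cumulative relaxation) — the
static grid values are inside training support by construction. NT1 sums
scaled range violations (≤ 0); for in-range points NT2 is the squared
Mahalanobis distance to the reference mean scaled by the reference
maximum. Any day containing a cell with ExDet > 1.15 or < −0.15 is
dropped whole.

Annual abundance is the mean of regional daily totals over included
days. Uncertainty is a parametric bootstrap over the coefficient
posterior N(β̂, V_β) (default B = 200): every included cell-day is
re-predicted per draw and the spread of annual means gives both an sd and
a 2.5–97.5% percentile interval; the percentile interval is the one to
use, since exp-scale abundance is right-skewed. The within-season spread
of the daily series is reported separately (the two answer different
questions and the literature rarely says which it combined). Long-term
hotspot maps are per-cell means and CV = sd/mean across included days;
zero-mean cells have undefined CV.

## Climate correlations

Monthly PDO/MEI-style indices are summarized as spring (February–May)
and summer (May–August) means — May deliberately in both. Lagged
cross-correlations (lag 0–10 yr) are plain Pearson correlations on the
overlapping pairs with a ±2/√n reference band; no prewhitening or
detrending by default (a detrend flag exists). Regressions are OLS
reporting R², F(1, n−2) and the two-sided p; with 31 paired years the
denominator degrees of freedom are 29. Rolling index variability is the
sample (n−1) sd over the w years strictly preceding each year (current
year excluded; w = 1 gives 0 by convention, flagged).

## The synthetic-data generator

Because no survey data are distributed, every input is generated with
known truth. The generator emulates: a 400 km north–south coastline with
Gaussian-bump capes (amplitude 10 km, alongshore scale 15 km — sized to
clear the 5 km detection threshold after 200 km smoothing) and > 300 ha
estuary points; bathymetry from a monotone cross-shore profile putting
the 200 m isobath at 9–21 km depending on latitude, multiplied by a
smooth random field (reefs and banks; without it depth would be an exact
function of distance-to-coast and shelf width and the additive model
could not attribute effects among them); patchy binary substrate; daily
CUTI as a seasonal sinusoid (negative winter, positive summer) plus
N(0, 0.3) noise per 1° bin; daily SST on a 0.25° grid with a seasonal
cycle, a latitude trend, and 1 °C anomalies (the mesoscale variability
that makes the SST effect separable from the equally seasonal upwelling
indices).

Surveys follow the field design: 20 km PSUs, four 5 km inshore segments
at random distances < 1500 m from shore, and a diagonal offshore transect
from the inshore boundary to the offshore limit (5 km north of the
mid-coast break, 3 km south), analysed as two segments covering the
inner and outer halves of the band. Four sweeps per year are worked
through over ~2.5 weeks each, spreading effort across 16 May–27 August.
Beaufort state is categorical with level 4 at 0.68% rarity; detection is
half-normal with σ from 450 m (BSS 0) to 240 m (BSS 4). Counts of whale
groups per segment are negative binomial (size 2; Poisson available) with
mean density × 2w × length / E[group size]; group sizes are 1 + Poisson(0.35);
perpendicular distances are uniform in the strip; 18% of sightings lose
their recorded distance. The default log-density truth combines a
declining distance-to-coast effect, positive shelf-width and SST effects,
a hard-substrate bonus, a null depth effect, and an upwelling–relaxation
interaction in which cumulative upwelling raises density only when
accompanied by relaxation days. Baseline density is set so a season
yields roughly 0.5 observed whales per segment — denser than the real
sparse surveys, deliberately, so that parameter-recovery tests are
informative at desk scale.

Not emulated: tides, within-season whale movement, responsive movement
to the vessel, distance measurement error, observer heterogeneity, and
spatial autocorrelation of counts beyond what the shared covariates
induce. Passing recovery tests therefore demonstrates the estimators
recover the data-generating process under the stated design — not that
real surveys are free of the biases those unmodelled features cause.

## Problem sizes used in the checks

The test suite runs surveys of 3–4 years (≈1400–1900 segments) on the
400 km coast, 100-replicate detection recoveries at n = 2000 distances,
50-replicate GAM shrinkage/dispersion loops, and a 25-replicate
end-to-end abundance recovery with B = 100 bootstrap draws; the
acceptance script uses 50 detection replicates and 8 end-to-end
replicates. These sizes were chosen to keep the whole suite comfortably
reproducible on a single CPU while leaving each statistical check with
enough replication to be meaningful.

## Known limitations

- The working-model REML (performance iteration) can differ slightly
  from a full Laplace-approximate REML; agreement with mgcv on test data
  is within a few percent in EDF and fitted values.
- Double-penalty shrinkage retains spurious EDF on a truly inert
  covariate in roughly a quarter to a third of replicates at these data
  sizes (see above); treat EDF-based selection as a screen, not a test.
- The percentile bootstrap propagates spatial-model coefficient
  uncertainty only; detection-stage uncertainty is not propagated into
  abundance intervals.
- ExDet's NT2 uses the training covariance; with strongly collinear
  dynamic covariates the Mahalanobis scaling can be unstable (a
  pseudo-inverse fallback with a warning handles the singular case).
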