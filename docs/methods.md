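# Methods

## The model

`pmgamm` fits generalized additive mixed models for monthly-average
particulate-matter concentrations over a large planar domain split into
contiguous regions. On the natural-log scale, for site *i*, month *t*, and
region *r*:

    log y_it = a + a_tr + Σ_q d_q(X_iq) + Σ_p f_pr(Z_itp)
               + g_tr(s_i) + g(s_i) + b_i + e_it,

    b_i ~ N(0, σ²_b),   e_it ~ N(0, σ²_e,rt),

where `X_iq` are time-invariant geographic covariates (elevation, urban land
use, population density, distance to road, point-source density), `Z_itp`
are time-varying covariates (smoothed monthly meteorology, and predicted
PM10 in the ratio variant), `d_q` and `f_pr` are 1-D penalized spline
smooths (basis dimension 10), `g_tr(s)` is a regional monthly (or seasonal)
thin-plate spatial surface, `g(s)` a domain-wide time-invariant surface,
`a_tr` a free monthly regional intercept, `b_i` unexplained site-level
variability, and `e_it` heteroscedastic region-month noise. The model
assumes additive covariate effects, stationary isotropic residual spatial
variation within a region, and independent normal residuals.

Three variants share this structure:

* **pm_direct / pm10_direct** — the response is the log monthly
  concentration; monthly regional surfaces.
* **ratio** — the response is ln(PM2.5 / predicted PM10); surfaces are
  per region-season (four seasons, winter = Dec–Feb), a 1-D temporal smooth
  `h(t)` of the month index is added to the joint stage, and predicted PM10
  enters as a time-varying covariate. Records with observed PM2.5 greater
  than 1.5 × predicted PM10 are deleted before fitting (strict inequality;
  the boundary case is kept). The exponentiated prediction is the ratio,
  truncated at one, and multiplied by predicted PM10.

## Two-stage estimation

Fitting is two-stage to keep the monthly panel tractable and to let
time-varying effects differ by region.

**Stage 1 (per region, with a 400 km buffer).** Sites of neighbouring
regions within 400 km of the region's boundary are included to suppress
boundary artefacts; their intercepts are discarded afterwards. The model

    log y_it = u_i + a_tr + Σ_p f_pr(Z_itp) [+ h(t)] + g_tr(s_i) + e_it

is estimated by back-fitting: (a) the joint step fits site indicators,
sum-to-zero month contrasts and the centred covariate smooths to the panel
minus the current spatial fits; (b) each month's (or season's) residuals get
a thin-plate surface with basis dimension floor(0.9 · sites present), GCV
smoothing with γ = 1.4 (1.8 in a designated sparse region). Sweeps alternate
until the maximum absolute change in fitted values falls below `tol`
(default 1e-4 on the log scale) or 20 sweeps. Smoothing parameters are
re-selected by GCV for the first 3 sweeps, then frozen.

When the site-indicator span overlaps the surface span heavily (few months,
dense bases), plain alternation converges slowly; the package applies
Anderson extrapolation (depth 5) to the sweep map once smoothing parameters
are frozen. The map is then linear, so the accelerated iteration converges
to the same fixed point as plain alternation — verified against the one-shot
penalized least-squares solution of the full combined design to 1e-6
relative error. A final plain sweep synchronises the stored surface
coefficients. `accelerate=False` recovers plain alternation, whose
convergence trace is monotone.

Identifiability conventions: `u_i` carries the site mean (no centring);
`a_tr` sums to zero across months within a region; each 1-D smooth is
column-centred over training rows; each surface is centred to mean zero over
its period's sites. These make `u_i` the adjusted long-term mean at the
site, which is what stage 2 models. σ²_e,rt is the per-region-month mean
squared residual. Fits are unweighted; the heteroscedastic variances feed
uncertainty, not weighting.

**Stage 2 (domain-wide).** The in-region site intercepts from all regions
are pooled and modelled as

    û_i = a + Σ_q d_q(X_iq) + g(s_i) + b_i,

with each `d_q` capped at 6 effective degrees of freedom (via its smoothing
parameter) and the spatial basis dimension following floor((I − Q) · 0.9).
That formula can exceed the number of sites once the covariate bases are
added, so the effective dimension is additionally capped to keep the total
coefficient count below I; both the requested and effective values are
stored. σ̂²_b is the residual variance. Regional interactions replace a
covariate's smooth by per-region-group smooths over one shared basis plus a
categorical region main effect; regions with fewer than 15 sites are pooled
with their nearest larger region.

## Penalized spline engine

* 1-D smooths are cubic B-splines with knots at quantiles of the distinct
  covariate values, extended (not clamped) at the boundaries, and a
  second-order difference penalty (P-splines). The penalty null space is
  2-dimensional; with equally spaced knots the infinite-smoothing limit is
  exactly the least-squares line.
* Spatial smooths are eigen-truncated thin-plate regression splines:
  the radial kernel r² log r on at most 600 distinct construction points
  (space-filling subset beyond that), truncated to k − 3 penalized
  directions plus the 3-dimensional polynomial null space. Coordinates are
  normalised internally (centred, scaled to unit RMS radius) so design
  columns are O(1) whatever the projection units — without this the normal
  equations mix scales of 1 and 10¹⁴ and solutions are unusable.
* Smoothing parameters minimise GCV, n·RSS/(n − γ·edf)², over a 41-point
  log-spaced grid on [1e-6, 1e6] per term with golden-section refinement;
  multi-term fits cycle coordinate-wise (2 sweeps). Models with a single
  penalized term use a simultaneous diagonalisation of (X'WX, S) that makes
  each λ evaluation O(p). GCV ties resolve toward the larger λ. γ ≥ 1
  inflates the effective degrees of freedom to deter over-fitting; it is
  applied to the meteorology surfaces and the stage-1 residual surfaces
  (1.4, or 1.8 for a sparse region), not to the stage-1 joint step or the
  stage-2 fit (default 1.0).
* The Bayesian posterior covariance σ̂²(X'WX + Σλ_j S_j)⁻¹ underlies all
  uncertainty. Wald tests on smooth terms use the statistic β'V⁻β with V⁻
  the covariance block's pseudo-inverse truncated to its leading
  round(edf) eigen-directions, referred to χ² with that many df; the
  truncation is what keeps the test near its nominal level (empirical
  type-I rate ≈ 0.07–0.08 at nominal 0.05 in the package's simulations).
  Interaction tests contrast group coefficient blocks over the shared basis
  the same way.

## Prediction and uncertainty

A log-scale prediction sums the stage-2 prediction at the location, the
monthly intercept, the time-varying smooths at (clamped) covariate values,
the monthly/seasonal surface, and `h(t)` for the ratio variant. Covariates
outside their training range are set to the training minimum or maximum —
globally for time-invariant covariates, within the site's region for
time-varying ones — and flagged. Prediction variance adds the stage-2
posterior prediction variance, the monthly-intercept variance, and the
surface prediction variance, treated as independent across stages (the
stages are estimated separately, so no cross-covariance is available);
observation-level variance optionally adds σ̂²_b + σ̂²_e,rt. The
uncertainty of the time-varying smooth values themselves is not propagated.

Native-scale means are exponentials; native SEs use the first-order delta
method, SE = exp(μ)·σ_log (within 10% of the Monte-Carlo SD for
σ_log ≤ 0.3). Direct variants report exponentiated log-scale 95% intervals.
The ratio chain propagates on the native scale: var(PM2.5) =
r²·var(PM10) + PM10²·var(r) under independence, coarse-fraction variance is
the sum of the two variances, and intervals are native-scale normal with the
lower bound floored at zero. Negative coarse predictions are retained but
flagged; validation excludes them and reports the count.

## Cross-validation and metrics

Sites are assigned at random, site-exclusively, to 10 folds; folds 1–9 are
scored and fold 10 is reserved during covariate selection to detect
selection-induced over-fitting. For sparse historical panels the
evaluation-year design is used instead: qualifying sites need at least 10
monthly values in the evaluation year and at least 70 overall (thresholds
are arguments; the defaults correspond to a 240-month panel), a withheld
subset equalises the evaluation year's fitting density with the historical
years (chosen among 25 seeded draws for best spatial coverage by max-min
nearest-neighbour distance), and only evaluation-year months are scored.

Metrics (native scale): CV R² (squared Pearson correlation), spatial CV R²
on per-site long-term means, CVMAE, major-axis regression (first principal
axis of the centred log-log cloud) of observations on predictions, 95%
prediction-interval coverage, and the normalized mean bias/error factors

    mean(M) ≥ mean(O):  NMBF = ΣM/ΣO − 1,   NMEF = Σ|M−O|/ΣO
    mean(M) <  mean(O):  NMBF = 1 − ΣO/ΣM,   NMEF = Σ|M−O|/ΣM

(×100%), which are sign-symmetric (halving and doubling give ±100%) and
satisfy NMEF ≥ |NMBF|. A residual-autocorrelation diagnostic averages
within-site ACFs per lag.

Covariate selection starts from a base term set, drops time-varying terms
that do not improve monthly CV R², greedily adds candidates that raise
spatial CV R² by more than 0.002 (configurable; candidates collinear with an
included term, |r| > 0.999, are refused), then removes Wald-insignificant
terms (p > 0.05) and terms whose fitted trend (top minus bottom quintile
means over the central 80% of the covariate range) contradicts an a-priori
declared direction. Every decision is recorded in an audit ledger.

## The synthetic-data generator

The generator emulates the structure the model assumes — it is the package's
study condition, not a calibration target. Defaults: 150 sites in 3
regions (600/7/60 in the large scenario), 24 monthly periods, 10%
missingness completely at random, explainable log-scale variance fraction
R²* = 0.8 split 30/70 between site-level (σ²_b) and observation-level noise,
with region-month noise factors uniform in [0.8, 1.2]. Covariate effects
are random centred tanh ramps (amplitude 0.35 for geographic, 0.25 for
meteorological covariates); spatial fields are sums of 5–20 Gaussian bumps
(SD-normalised amplitudes 0.30 domain-wide, 0.10 per region-month, seasonal
intercept amplitude 0.20). Monitoring sites cluster around urban centres;
elevation combines a regional bump field (SD 400 m) with site-scale relief
(SD 150 m), and urban land use and log population density correlate at
about 0.45 — enough shared structure to be realistic while keeping the
individual covariate effects identifiable (a near-collinear design would
make individual-smooth recovery meaningless, as real studies avoid
collinear covariate rosters for the same reason). The noise scale is set
from the realised signal variance so R²* hits its configured value exactly
in expectation.

The ratio process squashes an additive log-odds process (temporal trend,
seasonal regional fields, elevation effect, site and observation noise)
through a logistic so the true ratio lies in (0, 1), then contaminates a
configured fraction (default 0.3%) of records so PM2.5 > 1.5 × PM10,
exercising the outlier rule. The historical scenario thins early months to
a third of the network to exercise the evaluation-year CV design.

What the generator does not emulate: real GIS processing, network-specific
measurement error, spatially structured missingness, temporal
autocorrelation in e_it, non-stationary spatial covariance, and covariate
measurement error. Passing tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions, not performance on
real monitoring data.

## Problem sizes used by the tests and the acceptance script

Unit tests run on 20–150 sites and 3–24 months. The statistical acceptance
tests use: 20 sites × 3 months for back-fit/oracle equivalence (≤ 1e-6
relative); 10 seed replicates of the default 150-site scenario for smooth
recovery (pooled pointwise RMSE ≤ 0.07 per smooth, evaluated at observed
covariate values within the central 90% range); one 260-site, 24-month CV
run shared between the explainable-variance check (monthly CV R² within
[0.73, 0.87] of the configured R²* = 0.8; spatial ≥ monthly) and interval
calibration (coverage within [0.92, 0.98] on ~5000 left-out observations);
50 selection replicates at 120 sites; 500 replicates for the Wald type-I
rate. `scripts/acceptance.py` re-runs the default 150-site scenario end to
end (CV, ratio reconstruction, oracle and delta-method checks) with all
randomness derived from its `--seed`.

## Known limitations

* Back-fitting convergence is measured on fitted values, not coefficients;
  heavily confounded terms (e.g. a covariate whose seasonal mean mimics the
  monthly intercepts) have well-determined sums but individually uncertain
  components. The split between f(temperature) and a_tr is the main casualty
  in simulations.
* The two-stage variance composition ignores cross-stage covariance and the
  uncertainty in time-varying smooth values; synthetic coverage lands near
  0.95 regardless, and the ratio chain's first-order propagation
  over-covers slightly (≈ 0.97–1.0), consistent with delta-method inflation.
* GCV λ selection uses a grid with local refinement; profiles flat near the
  optimum can select different λ on different data orderings, so fits
  canonicalise row order internally.
* The Wald reference distribution (χ² with rounded edf) is approximate;
  empirical type-I rates run slightly above nominal (≈ 0.07 at 0.05).
* Tensor-product regional interaction smooths, REML selection, adaptive
  bases and real GIS ingestion are out of scope.
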