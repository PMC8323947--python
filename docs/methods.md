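# Methods

## The model

`countflux` analyses an annual count series — in its motivating
application, recorded conflicts among Classic Maya polities, 292–997 CE —
with a Bayesian Poisson state-space model:

    y_t      ~ Poisson(lambda_t)
    lambda_t = b_t * exp(X_t beta + delta_t)
    delta_t  ~ Normal(rho * delta_{t-1}, sigma)

`y_t` is the observed count in year `t`; `b_t` is a known exposure series
(monuments dated to that year), entering multiplicatively so the model
estimates conflicts **per monument** and is insulated from fluctuations in
how much record-keeping survived; `X_t` is a row of mean-centered
covariates (a summer sea-surface-temperature reconstruction and a
speleothem δ¹⁸O rainfall proxy) plus an intercept, on a log link; and
`delta_t` is a latent AR(1) log-rate path that absorbs the serial
dependence in the counts (cycles of retribution, in the archaeological
reading). The autoregression is deliberately covariate-free: a climate
perturbation raises this year's expected count but cannot compound into
future conflict through the latent process.

Priors are weakly informative: `beta ~ N(0, 1)` per coefficient,
`rho ~ N(0, 10)`, `delta0 ~ N(0, 10)` (the pre-sample latent level), and
`sigma ~ Exp(0.7)`. The second Normal parameter is read as a **variance**
(so `rho` and `delta0` have prior sd √10 ≈ 3.16). That reading is one
dataclass field; the sd-10 alternative is a one-line change and the
prior-sensitivity analysis (`prior_sensitivity`, which multiplies every
prior sd by a factor ≥ 1) covers the difference in practice. Under the
coefficient prior, the implied conflicts-per-monument intensity `exp(beta)`
exceeds 5 with probability ≈ 0.054 — the "rarely more than 5 per monument"
calibration the defaults are built around. `rho` is not constrained to
(−1, 1); the prior is its only regularizer.

Zero exposure is informative: `b_t = 0` forces `lambda_t = 0`, so a
positive count in a zero-monument year is impossible under the model and
is rejected during validation rather than silently patched.

## Model comparison

Four nested models differ only in which climate coefficients are free:
`baseline` (both pinned at zero — endogenous dynamics only),
`temperature`, `rainfall`, and `combined`. For nested models the Bayes
factor of the unrestricted against the restricted model is the
Savage-Dickey density ratio: prior density at zero over posterior density
at zero. The posterior density is estimated from the retained draws by a
Gaussian KDE with Silverman bandwidth (2-D product KDE at the origin for
`combined`); a normal-approximation estimator is available as a
cross-check (`normal_approx_bf`), and `kde_bandwidth_stability` flags a
run whose log-BF moves by more than 0.2 when the bandwidth is halved or
doubled. When the KDE mass at zero underflows, the BF is reported as
`+inf` with a warning — the coefficient is decisively nonzero.

Bayes factors map to a Jeffreys-style verbal scale with these cutoffs:
below 0.5 "supports baseline", 0.5–1.25 "indistinguishable", 1.25–5
"weak", 5–10 "moderate", 10–15 "substantial", above 15 "strong". The
classical wording leaves the band edges and the 5–10 range unnamed; the
cutoffs above are this package's documented convention, and
`interpret_bf` is monotone in the BF by construction.

`percent_effect(coef, dx) = 100·(e^(coef·dx) − 1)` converts a log-link
coefficient into the percent change in expected counts per covariate
shift — e.g. a coefficient of 1.49 per °C is a 16.07% rise per 0.1 °C.

## Posterior sampling

The sampler is adaptive random-walk Metropolis-within-Gibbs with four
non-obvious block types that the validity checks below motivated:

* **Scalar blocks** for each free coefficient, `rho`, and `sigma`
  (random walk on log σ with the Jacobian term). Proposal scales adapt
  toward ~30% acceptance during burn-in only and are frozen afterwards.
* **Checkerboard latent sweeps**: single-site proposals for `delta_t`,
  all even sites then all odd sites. Same-parity sites are conditionally
  independent given the other parity, so each half-sweep is a valid Gibbs
  block and vectorises; each site touches one Poisson term and two
  Gaussian terms.
* **Ridge moves**, one per coefficient: propose a shift `e` in the
  coefficient together with the counter-shift of the latent path that
  leaves every `lambda_t` — hence the likelihood — exactly unchanged
  (`delta - e` and `delta0 - e` for the intercept; `delta - e·x` for a
  covariate). Only the latent density and priors enter the ratio. These
  walk along the coefficient/path ridge that makes single-parameter
  updates in state-space models crawl; without them the intercept and
  coefficient chains fail the stationarity screen at any realistic budget.
* **A joint rescale move**: multiply `sigma`, the whole path and `delta0`
  by a common log-normal factor `c` (a scaling proposal; the Jacobian is
  `c^(T+2)`, and the latent-density ratio reduces to `−T log c`). This
  crosses the σ/path-amplitude funnel.
* **Exact Gaussian segment redraws**: over every maximal run of
  zero-exposure years the latent path has no likelihood terms, so its
  conditional given the run's anchors is a Gaussian AR bridge with
  tridiagonal precision. All bridged runs are stacked into one
  block-diagonal banded system and redrawn with a single banded Cholesky
  per iteration (a trailing run is forward-simulated). With the
  likelihood switched off this machinery redraws the whole path exactly.
  `delta0` gets a conjugate Gibbs draw (its conditional given `delta_1`,
  `rho`, `sigma` is normal).

Initialization: `empirical` (default) starts the path at
`log((y+0.5)/max(b,1))` minus its mean, `rho = 0.5`, `sigma` at the prior
mean; `zeros` zeroes everything except `sigma`. Retained draws default to
every post-burn-in iteration for top-level parameters and every 10th for
the latent path (storage). A fixed seed and config reproduce chains bit
for bit; suite fits derive per-model seeds as master seed + model index.

### Sampler validity checks

* *Conjugate slice*: with the path and all other parameters pinned, the
  intercept chain matches a fine-grid numerical posterior to total
  variation < 0.02.
* *Prior recovery*: with the likelihood off, the sampler reproduces the
  prior moments of every top-level parameter. This check runs at **T = 3**:
  under `rho ~ N(0, 10)` most prior mass sits on explosive AR regimes
  whose paths grow like `rho^T`, and for long series no local sampler can
  traverse between the stationary and explosive parts of that joint
  distribution — at T = 3 the geometry is benign and all moments recover.
  This is a property of the check, not of posterior inference, where the
  data keep `rho` in a well-identified region.
* *Ridge-move neutrality*: long runs with the ridge moves disabled give
  the same posteriors, confirming the moves change mixing, not the target.
* *AR bridge*: the segment redraw matches the closed-form conditional
  mean and covariance of an AR(1) bridge.

## Convergence and summaries

`geweke_z` compares the first 10% and last 50% of a chain:
`z = (mean_f − mean_l) / sqrt(svar_f/n_f + svar_l/n_l)`, with segment
variances from a batch-means estimator (batch size ≈ √n), which is robust
to the autocorrelation MCMC chains carry. |z| < 2 on every top-level
parameter is the convergence gate applied to the reference fit; a
constant segment raises a degenerate-chain error rather than returning a
misleading z.

`summarize_posterior` reports the mean, sd and 68%/95% highest-density
intervals (shortest intervals at each mass, via `arviz.hdi`); the 68%
interval is clipped into the 95% one in the measure-zero cases where
empirical shortest intervals of a multimodal sample would fail to nest.
Figures shade exactly these intervals, so plots and tables cannot
disagree.

## Proxy annualization

Subannual proxy records are interpolated with a natural cubic spline
through all points and averaged over each calendar year, with year `Y`
owning `[Y, Y+1)`. The default average is the exact integral of the
spline over the year — the limit of averaging ever-finer regular
evaluation grids; a finite Simpson grid (`points_per_year`) is available
and converges to the exact value as the grid refines. Whether the original
workflow averaged fine-grid evaluations or used annual knots is not
recoverable from its description; the integral-average is this package's
documented choice. Covariate means are taken over the analysis window
(after `align_window`), because centering is part of the regression
design; interior missing years are an error, never interpolated.

## The synthetic-data generator

`generate_dataset` emulates the study design so every stage is testable
without the original archive:

* **Temperature-like covariate**: linear drift 0.0025 units/yr (≈ 1 °C
  across the default 400-year series, the order of magnitude of
  first-millennium SST reconstructions) plus AR(0.8) noise with
  innovation sd 0.03.
* **Rainfall-like covariate**: no drift, AR(0.7) noise with innovation sd
  0.12 — noisier and trendless, like an annualized δ¹⁸O record (values in
  tenths of a unit).
* **Monuments**: Poisson counts around a smooth intensity bump (width
  0.22 of the series) that is near zero early, peaks at `base_rate` = 4
  per year at 60% of the series, and declines — reproducing the early
  sparsity (long zero runs) and late-period density of the epigraphic
  record. A `flat` shape and an explicit `monument_series` override exist
  for controlled experiments.
* **Conflicts**: drawn from the state-space model itself around a
  simulated latent path, with defaults `beta = (1.5, 0)` on centered
  covariates, `rho = 0.8`, `sigma = 0.3`, `delta0 = 0`, intercept 0.

One master seed spawns independent sub-streams per series, so each
component is reproducible alone. Ground truth (path and parameters) is
always returned: parameter recovery is the package's main validation
surface.

What the generator does **not** emulate: the actual epigraphic event
dates, monument-dating uncertainty, the speleothem age model, or any
feedback from climate into the latent process. Passing recovery tests
therefore shows the estimator is correct for data that satisfy the model
assumptions — it does not validate those assumptions for any real record.

## Problem sizes and budgets

The reference protocol is 1,000,000 iterations with the first 1,000
discarded (the `McmcConfig` defaults). The test suite and acceptance
script run scaled-down budgets the diagnostics show are ample at these
problem sizes: 10⁵ iterations for the reference fit (T = 400) and
2.1×10⁴ iterations (2×10⁴ retained) per model for the 20-replicate
recovery study. The recovery study checks that 95% intervals cover the
generating `beta_temperature`, `rho`, `sigma` in at least 17 of 20
replicate worlds and that the model suite prefers the temperature model
(BF > 5 and above the rainfall BF) in at least 18.

## Known limitations

* Savage-Dickey BFs inherit KDE error where the posterior at zero is far
  in a tail; the reported value is then a lower-accuracy estimate of a
  very large number (the verbal category is insensitive to this).
* Single-chain diagnostics only (Geweke + traces); no multi-chain R-hat.
* The latent path summary stores thinned draws; per-year HDIs at full
  resolution require lowering `latent_thin`.
* `rho` is unbounded, so fits to very short or empty series can wander
  into explosive regimes where only the prior constrains them.
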