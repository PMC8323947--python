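# countflux

Bayesian Poisson state-space analysis of annual count time series with
exposure offsets, climate covariates, a latent autocorrelated conflict
process, and Savage-Dickey model comparison.

The package grew out of a concrete question in archaeological
paleoclimatology — did temperature or rainfall drive the rise in recorded
conflict among Classic Maya polities between 292 and 997 CE? — but the
machinery is generic: any annual count series with a known exposure
series and candidate covariates fits.

## The model

Observed counts are Poisson around an exposure-scaled log-linear rate
with a latent AR(1) component:

    y_t      ~ Poisson(lambda_t)
    lambda_t = b_t * exp(X_t * beta + delta_t)
    delta_t  ~ Normal(rho * delta_{t-1}, sigma)

* `b_t` — exposure (monuments dated to year t), so the model estimates
  counts *per monument* and is robust to record-survival fluctuations;
* `X_t` — mean-centered covariates (temperature and rainfall proxies)
  plus an intercept, on a log link;
* `delta_t` — latent endogenous log-rate: serial dependence (retributive
  cycles) lives here, and covariates cannot feed back into it.

Priors: `beta ~ N(0,1)`, `rho ~ N(0,10)`, `delta0 ~ N(0,10)` (variance
parameterisation), `sigma ~ Exp(0.7)`. Inference is MCMC over the
coefficients, `rho`, `sigma`, `delta0` and the whole latent path. Four
nested models (baseline / temperature / rainfall / combined) are compared
with Savage-Dickey Bayes factors — prior over posterior density at the
pinned-to-zero coefficient — read on a Jeffreys-style verbal scale.
See `docs/methods.md` for the full account.

## A worked example

`examples/compare_models.py` simulates the package's reference scenario —
400 years, a true temperature effect of 1.5 (log-link, per unit), no true
rainfall effect, latent AR(1) with rho 0.8 and sigma 0.3, and an
epigraphic-style exposure series that is all zeros for the first ~35
years — then fits all four models and prints the comparison:

```
      model  bayes_factor  temperature_coefficient  rainfall_coefficient          category
   baseline         1.000                      NaN                   NaN indistinguishable
temperature       154.811                    1.389                   NaN            strong
   rainfall         0.286                      NaN                 0.030 supports baseline
   combined        28.612                    1.398                 0.042            strong

The data were generated with a true temperature effect (1.5) and no
rainfall effect, so the temperature model should earn a large Bayes
factor ('strong' evidence) and the rainfall model should not.

posterior-mean temperature coefficient: 1.39 per unit;
that is a 14.9% change in expected conflicts per 0.1-unit warming
```

Reading it: the temperature model is ~150 times more probable than
the baseline (strong evidence), the rainfall model is slightly *less*
probable than the baseline, and the recovered coefficient (1.39, truth
1.5) translates through the log link into ~15% more expected conflicts
per 0.1 units of warming. On the published Classic Maya record the same
pipeline reading would be: temperature coefficient 1.49 → a 16.07% rise
per 0.1 °C.

Other examples: `simulate_dataset.py` (the generator and its ground
truth), `fit_state_space_model.py` (one fit with posterior summaries and
Geweke diagnostics), `annualize_proxy_record.py` (subannual proxy →
annual means), `full_pipeline.py` (config-driven end-to-end run with a
wider-prior sensitivity pass).

## Command line

A thin CLI wraps the library for shell use:

```sh
countflux simulate --n-years 400 --seed 1 --out data.csv
countflux prep --conflicts raw.csv --proxy rainfall d18o.csv --start 292 --end 997 --out data.csv
countflux fit --data data.csv --model temperature --iters 100000 --seed 1 --out chains/
countflux diagnose --chains chains/
countflux compare --data data.csv --iters 100000 --seed 1 --out table.csv
countflux run --config analysis.yml --out results/
```

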