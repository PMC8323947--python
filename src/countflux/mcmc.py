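"""Posterior sampling for the Poisson state-space model.

The sampler is an adaptive random-walk Metropolis-within-Gibbs scheme:

* one scalar random-walk block per regression coefficient, plus blocks for
  ``rho``, ``sigma`` (random walk on log sigma with the Jacobian
  correction) and ``delta0``;
* the latent path is updated by single-site proposals swept in an
  even/odd checkerboard: given its neighbours, each ``delta_t`` depends on
  only two latent-density terms and one Poisson term, and sites of the
  same parity are conditionally independent, so each half-sweep is a valid
  Gibbs block that vectorises over the whole series;
* a joint rescale block multiplies ``sigma``, the whole latent path and
  ``delta0`` by a common log-normal factor (a scaling proposal with the
  ``c^(T+2)`` Jacobian correction), which moves the sampler through the
  sigma/path-amplitude funnel that single-site updates crawl along;
* one "ridge" block per regression coefficient proposes a joint move that
  shifts the coefficient and counter-shifts the latent path so the Poisson
  mean — and hence the likelihood — is exactly unchanged.  Only the latent
  density and priors enter the acceptance ratio.  These moves walk along
  the coefficient/latent-path ridge that plagues single-parameter updates
  in state-space models and are what make the intercept and covariate
  coefficients mix well.

Proposal scales adapt toward a 20-45% acceptance window during burn-in
only and are frozen afterwards, preserving detailed balance for the
retained draws.  All randomness flows from a single ``numpy`` Generator,
so a fixed seed and config reproduce chains bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal
from scipy.linalg import cho_solve_banded, cholesky_banded, solve_banded

from .exceptions import (
    ConfigError,
    DegenerateChainError,
    InitializationError,
    ValidationError,
)
from .model import ModelSpec, PriorSpec

#: clip on log-mean changes before expm1: beyond this the move is rejected
#: on likelihood grounds anyway and exp() would overflow
_EXPM1_CLIP = 600.0

__all__ = [
    "McmcConfig",
    "PosteriorChains",
    "run_mcmc",
    "geweke_z",
    "geweke_table",
    "summarize_posterior",
]


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    The default budget mirrors the full analysis protocol (one million
    iterations, the first thousand discarded as burn-in); tests and the
    synthetic benchmark use ~1e5 iterations, which the recovery and
    convergence checks show is ample at T of a few hundred years.
    """

    n_iterations: int = 1_000_000
    burn_in: int = 1_000
    thin: int = 1
    latent_thin: int = 10
    seed: int = 0
    adapt_interval: int = 50
    init_strategy: str = "empirical"
    target_acceptance: float = 0.3

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be positive")
        if self.burn_in < 0 or self.burn_in >= self.n_iterations:
            raise ConfigError("burn_in must satisfy 0 <= burn_in < n_iterations")
        if self.thin < 1 or self.latent_thin < 1:
            raise ConfigError("thin and latent_thin must be >= 1")
        if self.adapt_interval < 1:
            raise ConfigError("adapt_interval must be >= 1")
        if self.init_strategy not in ("zeros", "empirical"):
            raise ConfigError("init_strategy must be 'zeros' or 'empirical'")
        if not 0.0 < self.target_acceptance < 1.0:
            raise ConfigError("target_acceptance must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PosteriorChains:
    """Retained MCMC draws plus run metadata.

    ``draws`` holds one column per top-level parameter; ``latent`` holds
    the (time-thinned) latent path draws, one row per retained latent
    sample.  ``acceptance`` maps block names to post-burn-in acceptance
    rates.
    """

    draws: pd.DataFrame
    latent: np.ndarray
    acceptance: dict
    config: McmcConfig
    model: ModelSpec
    priors: PriorSpec

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(self.draws.columns)

    @property
    def n_retained(self) -> int:
        return len(self.draws)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[name].to_numpy()

    def geweke(self, **kw) -> pd.DataFrame:
        return geweke_table(self, **kw)

    def summary(self, hdr_levels=(0.68, 0.95)) -> pd.DataFrame:
        rows = {}
        for name in self.parameter_names:
            s = summarize_posterior(self[name], hdr_levels=hdr_levels)
            row = {"mean": s["mean"], "sd": s["sd"]}
            for lev, (lo, hi) in s["hdr"].items():
                row[f"hdr{int(round(lev * 100))}_low"] = lo
                row[f"hdr{int(round(lev * 100))}_high"] = hi
            rows[name] = row
        return pd.DataFrame(rows).T

    def manifest(self) -> dict:
        gw = self.geweke()
        return {
            "config": self.config.to_dict(),
            "model": self.model.to_dict(),
            "priors": self.priors.to_dict(),
            "acceptance": {
                k: (v if isinstance(v, dict) else float(v))
                for k, v in self.acceptance.items()
            },
            "geweke_z": {k: float(v) for k, v in zip(gw.index, gw["z"])},
            "n_retained": int(self.n_retained),
        }

    def save(self, directory) -> Path:
        import json

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.draws.to_csv(directory / "chains.csv", index=False)
        pd.DataFrame(self.latent).to_csv(directory / "latent.csv", index=False)
        with open(directory / "manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=2)
        return directory

    @classmethod
    def load(cls, directory) -> "PosteriorChains":
        """Rebuild chains (draws, latent path, metadata) from a saved run."""
        import json

        directory = Path(directory)
        draws = pd.read_csv(directory / "chains.csv")
        latent = pd.read_csv(directory / "latent.csv").to_numpy()
        with open(directory / "manifest.json") as fh:
            man = json.load(fh)
        model = ModelSpec(
            covariate_names=tuple(man["model"]["covariate_names"]),
            free_mask=tuple(man["model"]["free_mask"]),
            name=man["model"]["name"],
        )
        return cls(
            draws=draws,
            latent=latent,
            acceptance=man["acceptance"],
            config=McmcConfig(**man["config"]),
            model=model,
            priors=PriorSpec.from_dict(man["priors"]),
        )


def _ar_bridge_draw(
    rho: float, sigma: float, left: float, right: float, m: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact draw of m consecutive AR(1) states given both anchor values.

    The conditional is Gaussian with a tridiagonal precision matrix; the
    draw uses a banded Cholesky factor (O(m)).
    """
    inv = 1.0 / sigma**2
    ab = np.zeros((2, m))
    ab[1, :] = (1.0 + rho * rho) * inv
    ab[0, 1:] = -rho * inv
    h = np.zeros(m)
    h[0] += rho * left * inv
    h[-1] += rho * right * inv
    U = cholesky_banded(ab, lower=False)
    mean = cho_solve_banded((U, False), h)
    return mean + solve_banded((0, 1), U, rng.standard_normal(m))


def _initial_state(y, b, k, priors: PriorSpec, strategy: str):
    beta = np.zeros(k)
    sigma = 1.0 / priors.sigma_rate  # prior mean; sigma must start positive
    if strategy == "zeros":
        return beta, 0.0, sigma, 0.0, np.zeros(len(y))
    delta = np.log((y + 0.5) / np.maximum(b, 1.0))
    delta -= delta.mean()
    return beta, 0.5, sigma, 0.0, delta


def run_mcmc(
    dataset,
    model_spec: ModelSpec | None = None,
    prior_spec: PriorSpec | None = None,
    mcmc_config: McmcConfig | None = None,
    *,
    include_likelihood: bool = True,
    update_latent: bool = True,
    use_ridge_moves: bool = True,
    fixed: Mapping | None = None,
) -> PosteriorChains:
    """Sample the joint posterior of (beta, rho, sigma, delta0, delta_1:T).

    ``dataset`` is a TimeSeriesDataset (free covariates are mean-centered
    internally before entering the design — a no-op when already
    centered).  Coefficients outside ``model_spec``'s free set are held at
    exactly zero by never entering the design.

    The keyword-only switches support sampler-validation experiments:
    ``include_likelihood=False`` targets the prior alone (prior-recovery
    check), ``update_latent=False`` freezes the latent path, and ``fixed``
    pins named parameters (``"rho"``, ``"sigma"``, ``"delta0"``,
    ``"intercept"``, ``"beta_<covariate>"``, or ``"delta"`` for the whole
    path) at given values.
    """
    priors = prior_spec or PriorSpec()
    config = mcmc_config or McmcConfig()
    fixed = dict(fixed or {})
    if model_spec is None:
        model_spec = ModelSpec(
            covariate_names=dataset.covariate_names,
            free_mask=(True,) * len(dataset.covariate_names),
            name="all-free",
        )

    y = np.asarray(dataset.conflicts, dtype=float)
    b = np.asarray(dataset.monuments, dtype=float)
    T = len(y)
    X = model_spec.design_matrix(dataset.covariates)
    X[:, 1:] -= X[:, 1:].mean(axis=0)  # idempotent mean-centering
    k = X.shape[1]

    active = b > 0
    if include_likelihood and np.any(y[~active] > 0):
        bad = np.flatnonzero(~active & (y > 0))
        raise InitializationError(
            "initial density is -inf: positive counts with zero exposure at "
            f"rows {bad.tolist()[:10]}; clean the data or clamp the exposure"
        )

    beta, rho, sigma, delta0, delta = _initial_state(
        y, b, k, priors, config.init_strategy
    )
    labels = model_spec.parameter_labels
    for name, value in fixed.items():
        if name == "delta":
            delta = np.asarray(value, dtype=float).copy()
            if delta.shape != (T,):
                raise ConfigError("fixed delta path must have length T")
        elif name == "rho":
            rho = float(value)
        elif name == "sigma":
            sigma = float(value)
            if sigma <= 0:
                raise ConfigError("fixed sigma must be positive")
        elif name == "delta0":
            delta0 = float(value)
        elif name in labels[:k]:
            beta[labels.index(name)] = float(value)
        else:
            raise ConfigError(f"cannot fix unknown parameter {name!r}")

    rng = np.random.default_rng(config.seed)

    # --- likelihood bookkeeping on the active (b > 0) subset ------------
    act_idx = np.flatnonzero(active)
    ya = y[act_idx]
    Xa = X[act_idx]
    logba = np.log(b[act_idx])
    if include_likelihood:
        lam_a = np.exp(logba + Xa @ beta + delta[act_idx])
    else:
        ya = np.zeros_like(ya)
        lam_a = np.zeros(len(act_idx))  # zero likelihood terms everywhere
    yX = ya @ Xa  # constant: d loglik / d beta_j linear term

    # prev[t] = delta_{t-1}, prev[0] = delta0
    prev = np.empty(T)
    prev[0] = delta0
    prev[1:] = delta[:-1]

    # --- checkerboard sweep precomputation -------------------------------
    sweeps = []
    pos_in_active = np.full(T, -1)
    pos_in_active[act_idx] = np.arange(len(act_idx))
    for start in (0, 1):
        S = np.arange(start, T, 2)
        lampos = pos_in_active[S]  # -1 where inactive
        has_next = S + 1 < T
        sweeps.append(
            {
                "S": S,
                "yS": y[S] if include_likelihood else np.zeros(len(S)),
                "lampos": lampos,
                "act": lampos >= 0,
                "has_next": has_next,
                "next": (S + 1)[has_next],
            }
        )

    # maximal runs of zero-exposure sites (everything, with likelihood off):
    # these get exact Gaussian segment redraws instead of crawling site-wise
    run_mask = ~active if include_likelihood else np.ones(T, dtype=bool)
    inactive_runs = []
    t = 0
    while t < T:
        if run_mask[t]:
            a = t
            while t + 1 < T and run_mask[t + 1]:
                t += 1
            inactive_runs.append((a, t))
        t += 1
    # all runs with a right anchor share one block-diagonal tridiagonal
    # system, so a single banded Cholesky redraws every bridged segment
    bridged = [(a, bb) for a, bb in inactive_runs if bb < T - 1]
    tail_run = next(((a, bb) for a, bb in inactive_runs if bb == T - 1), None)
    if bridged:
        seg_sites = np.concatenate([np.arange(a, bb + 1) for a, bb in bridged])
        n_seg = len(seg_sites)
        # off-diagonal coupling exists only inside a segment
        couple = np.ones(n_seg - 1, dtype=bool) if n_seg > 1 else np.zeros(0, bool)
        pos = 0
        first_pos, last_pos, left_site, right_site = [], [], [], []
        for a, bb in bridged:
            m = bb - a + 1
            first_pos.append(pos)
            last_pos.append(pos + m - 1)
            left_site.append(a - 1)  # -1 encodes the delta0 anchor
            right_site.append(bb + 1)
            if pos + m - 1 < n_seg - 1:
                couple[pos + m - 1] = False
            pos += m
        first_pos = np.array(first_pos)
        last_pos = np.array(last_pos)
        left_site = np.array(left_site)
        right_site = np.array(right_site)
        seg_next = seg_sites + 1
        seg_next = seg_next[seg_next < T]

    # --- blocks and adaptation -------------------------------------------
    scalar_names = list(labels[:k]) + ["rho", "sigma"]
    free_scalar = [
        name
        for name in scalar_names
        if name not in fixed
    ]
    do_latent = update_latent and "delta" not in fixed
    # ridge blocks: joint (coefficient, latent path) moves that leave the
    # likelihood invariant; only sensible when the path itself is sampled
    ridge_js = (
        [j for j in range(k) if labels[j] not in fixed]
        if (do_latent and use_ridge_moves)
        else []
    )
    Xprev = np.zeros_like(X)
    Xprev[1:] = X[:-1]
    Xprev[0, 0] = 1.0  # the intercept ridge also shifts delta0, so prev[0] moves
    ridge_scales = {j: 0.5 for j in ridge_js}
    window_ridge = {j: 0 for j in ridge_js}
    do_rescale = do_latent and "sigma" not in fixed and "delta0" not in fixed
    rescale_scale = 0.1
    window_rescale = 0
    scales = {}
    for name in free_scalar:
        scales[name] = 0.3 if name == "sigma" else 0.1
    latent_scale = 0.5
    window_acc = {name: 0 for name in free_scalar}
    window_lat_acc = 0.0
    total_acc = {name: 0 for name in free_scalar}
    total_lat_acc = 0.0
    n_post = 0

    inv_beta_var = 1.0 / priors.beta_sd**2
    inv_rho_var = 1.0 / priors.rho_sd**2
    inv_d0_var = 1.0 / priors.delta0_sd**2

    n_ret = (config.n_iterations - config.burn_in + config.thin - 1) // config.thin
    param_out = np.empty((n_ret, k + 3))
    lat_every = config.thin * config.latent_thin
    n_lat = (config.n_iterations - config.burn_in + lat_every - 1) // lat_every
    latent_out = np.empty((n_lat, T)) if do_latent or True else None
    ret_i = 0
    lat_i = 0

    idx_of = {name: i for i, name in enumerate(scalar_names)}
    nb = len(free_scalar)

    for it in range(config.n_iterations):
        z = rng.standard_normal(nb)
        logu = np.log(rng.random(nb))
        for bi, name in enumerate(free_scalar):
            s = scales[name]
            j = idx_of[name]
            if j < k:  # a regression coefficient
                ds = s * z[bi]
                dloglik = ds * yX[j] - lam_a @ np.expm1(Xa[:, j] * ds)
                old = beta[j]
                dlogpri = -0.5 * inv_beta_var * (
                    (old + ds - priors.beta_mean) ** 2 - (old - priors.beta_mean) ** 2
                )
                if logu[bi] < dloglik + dlogpri:
                    beta[j] = old + ds
                    lam_a *= np.exp(Xa[:, j] * ds)
                    window_acc[name] += 1
            elif name == "rho":
                dr = s * z[bi]
                Sdp = delta @ prev
                Spp = prev @ prev
                new, old = rho + dr, rho
                dssr = (-2.0 * Sdp * (new - old) + (new**2 - old**2) * Spp)
                dlp = -0.5 * dssr / sigma**2 - 0.5 * inv_rho_var * (
                    (new - priors.rho_mean) ** 2 - (old - priors.rho_mean) ** 2
                )
                if logu[bi] < dlp:
                    rho = new
                    window_acc[name] += 1
            elif name == "sigma":
                step = s * z[bi]
                new = sigma * math.exp(step)
                resid = delta - rho * prev
                ssr = resid @ resid
                dlp = (
                    -T * (math.log(new) - math.log(sigma))
                    - 0.5 * ssr * (1.0 / new**2 - 1.0 / sigma**2)
                    - priors.sigma_rate * (new - sigma)
                    + step  # Jacobian of the log-scale walk
                )
                if logu[bi] < dlp:
                    sigma = new
                    window_acc[name] += 1

        if do_latent and include_likelihood:
            inv2s2 = 0.5 / sigma**2
            lat_acc_count = 0
            n_sites = 0
            for sw in sweeps:
                S = sw["S"]
                m = len(S)
                eps = latent_scale * rng.standard_normal(m)
                dS = delta[S]
                r0 = dS - rho * prev[S]
                dlp = -inv2s2 * ((r0 + eps) ** 2 - r0**2)
                hn = sw["has_next"]
                r1 = delta[sw["next"]] - rho * dS[hn]
                e1 = eps[hn]
                dlp[hn] += -inv2s2 * ((r1 - rho * e1) ** 2 - r1**2)
                lamS = np.zeros(m)
                actm = sw["act"]
                lamS[actm] = lam_a[sw["lampos"][actm]]
                dll = sw["yS"] * eps - lamS * np.expm1(eps)
                acc = np.log(rng.random(m)) < dlp + dll
                if acc.any():
                    sites = S[acc]
                    delta[sites] += eps[acc]
                    nxt = sites + 1
                    nxt = nxt[nxt < T]
                    prev[nxt] = delta[nxt - 1]
                    upd = acc & actm
                    if upd.any():
                        lam_a[sw["lampos"][upd]] *= np.exp(eps[upd])
                lat_acc_count += int(acc.sum())
                n_sites += m
            window_lat_acc += lat_acc_count / n_sites

        if do_latent and bridged:
            # exact Gibbs redraw of the latent path over zero-exposure runs
            # (the whole path when the likelihood is switched off): given its
            # anchors, each segment is purely Gaussian under the AR process,
            # and all segments form one block-diagonal tridiagonal system
            inv = 1.0 / sigma**2
            ab = np.zeros((2, n_seg))
            ab[1] = (1.0 + rho * rho) * inv
            ab[0, 1:] = np.where(couple, -rho * inv, 0.0)
            h = np.zeros(n_seg)
            lvals = np.where(left_site >= 0, delta[left_site], delta0)
            h[first_pos] += rho * inv * lvals
            h[last_pos] += rho * inv * delta[right_site]
            U = cholesky_banded(ab, lower=False)
            mean = cho_solve_banded((U, False), h)
            delta[seg_sites] = mean + solve_banded(
                (0, 1), U, rng.standard_normal(n_seg)
            )
            prev[seg_next] = delta[seg_next - 1]

        if do_latent and tail_run is not None:
            # the trailing zero-exposure run has no right anchor:
            # forward-simulate it from the AR recursion
            a, bb = tail_run
            m = bb - a + 1
            innov = sigma * rng.standard_normal(m)
            innov[0] += rho * (delta[a - 1] if a > 0 else delta0)
            delta[a:] = signal.lfilter([1.0], [1.0, -rho], innov)
            prev[a + 1 :] = delta[a:-1]

        if "delta0" not in fixed:
            # conjugate Gibbs draw: delta0 | delta_1, rho, sigma is normal
            prec = inv_d0_var + rho * rho / sigma**2
            mu = (
                inv_d0_var * priors.delta0_mean + rho * delta[0] / sigma**2
            ) / prec
            delta0 = mu + rng.standard_normal() / math.sqrt(prec)
            prev[0] = delta0

        if do_rescale:
            # joint scaling move: (sigma, delta, delta0) -> c * (...)
            # residuals scale with sigma, so the latent density contributes
            # exactly -T log c; the Jacobian of the T+2-dim scaling is c^(T+2)
            s = rescale_scale * rng.standard_normal()
            c = math.exp(s)
            d_act = np.clip((c - 1.0) * delta[act_idx], -_EXPM1_CLIP, _EXPM1_CLIP)
            dll = ya @ d_act - lam_a @ np.expm1(d_act)
            new_d0 = c * delta0
            dlp = (
                dll
                + 2.0 * s  # -T log c from the latent density + (T+2) log c Jacobian
                - priors.sigma_rate * sigma * (c - 1.0)
                - 0.5
                * inv_d0_var
                * ((new_d0 - priors.delta0_mean) ** 2 - (delta0 - priors.delta0_mean) ** 2)
            )
            if math.log(rng.random()) < dlp:
                sigma *= c
                delta *= c
                delta0 = new_d0
                prev *= c
                lam_a *= np.exp(d_act)
                window_rescale += 1

        if ridge_js:
            ze = rng.standard_normal(len(ridge_js))
            logue = np.log(rng.random(len(ridge_js)))
            for ri, j in enumerate(ridge_js):
                e = ridge_scales[j] * ze[ri]
                xcol = X[:, j]
                xprev = Xprev[:, j]
                w = xcol - rho * xprev
                r = delta - rho * prev
                dlp = -(0.5 / sigma**2) * (e**2 * (w @ w) - 2.0 * e * (r @ w))
                old = beta[j]
                dlp += -0.5 * inv_beta_var * (
                    (old + e - priors.beta_mean) ** 2 - (old - priors.beta_mean) ** 2
                )
                if j == 0:
                    dlp += -0.5 * inv_d0_var * (
                        (delta0 - e - priors.delta0_mean) ** 2
                        - (delta0 - priors.delta0_mean) ** 2
                    )
                if logue[ri] < dlp:
                    beta[j] = old + e
                    delta -= e * xcol
                    prev -= e * xprev
                    if j == 0:
                        delta0 -= e
                    window_ridge[j] += 1

        # adaptation during burn-in only
        if it < config.burn_in:
            if (it + 1) % config.adapt_interval == 0:
                for name in free_scalar:
                    rate = window_acc[name] / config.adapt_interval
                    scales[name] = float(
                        np.clip(
                            scales[name]
                            * math.exp(1.2 * (rate - config.target_acceptance)),
                            1e-5,
                            100.0,
                        )
                    )
                    window_acc[name] = 0
                for j in ridge_js:
                    rate = window_ridge[j] / config.adapt_interval
                    ridge_scales[j] = float(
                        np.clip(
                            ridge_scales[j]
                            * math.exp(1.2 * (rate - config.target_acceptance)),
                            1e-5,
                            100.0,
                        )
                    )
                    window_ridge[j] = 0
                if do_rescale:
                    rate = window_rescale / config.adapt_interval
                    rescale_scale = float(
                        np.clip(
                            rescale_scale
                            * math.exp(1.2 * (rate - config.target_acceptance)),
                            1e-5,
                            100.0,
                        )
                    )
                    window_rescale = 0
                if do_latent:
                    rate = window_lat_acc / config.adapt_interval
                    latent_scale = float(
                        np.clip(
                            latent_scale
                            * math.exp(1.2 * (rate - config.target_acceptance)),
                            1e-5,
                            100.0,
                        )
                    )
                    window_lat_acc = 0.0
        else:
            if it == config.burn_in:
                for name in free_scalar:
                    window_acc[name] = 0
                for j in ridge_js:
                    window_ridge[j] = 0
                window_rescale = 0
                window_lat_acc = 0.0
            n_post += 1
            rel = it - config.burn_in
            if rel % config.thin == 0:
                param_out[ret_i, :k] = beta
                param_out[ret_i, k] = rho
                param_out[ret_i, k + 1] = sigma
                param_out[ret_i, k + 2] = delta0
                ret_i += 1
            if rel % lat_every == 0:
                latent_out[lat_i] = delta
                lat_i += 1

    # post-burn-in acceptance bookkeeping (counters accumulate after reset)
    acceptance = {}
    if n_post > 0:
        for name in free_scalar:
            acceptance[name] = window_acc[name] / n_post
        for j in ridge_js:
            acceptance[f"ridge_{labels[j]}"] = window_ridge[j] / n_post
        if do_rescale:
            acceptance["rescale"] = window_rescale / n_post
        if do_latent:
            acceptance["latent"] = window_lat_acc / n_post
    acceptance["scales"] = {**{n: scales[n] for n in free_scalar}}
    for j in ridge_js:
        acceptance["scales"][f"ridge_{labels[j]}"] = ridge_scales[j]
    if do_latent:
        acceptance["scales"]["latent"] = latent_scale

    draws = pd.DataFrame(param_out[:ret_i], columns=list(labels))
    return PosteriorChains(
        draws=draws,
        latent=latent_out[:lat_i],
        acceptance=acceptance,
        config=config,
        model=model_spec,
        priors=priors,
    )


def _batch_means_variance(segment: np.ndarray) -> float:
    """Spectral variance (variance of the mean times n) via batch means.

    Robust to autocorrelation: the segment is cut into ~sqrt(n) batches
    and the variance of batch means, scaled by the batch size, estimates
    the spectral density of the chain at frequency zero.
    """
    n = len(segment)
    bsize = max(1, int(math.sqrt(n)))
    nb = n // bsize
    means = segment[: nb * bsize].reshape(nb, bsize).mean(axis=1)
    return float(np.var(means, ddof=1) * bsize)


def geweke_z(chain, first_fraction: float = 0.1, last_fraction: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain segments.

    ``z = (mean_first - mean_last) / sqrt(svar_f/n_f + svar_l/n_l)`` with
    segment variances from an autocorrelation-robust batch-means estimator.
    Under stationarity z is asymptotically standard normal; |z| well above
    2 flags a drifting chain.
    """
    chain = np.asarray(chain, dtype=float)
    n = len(chain)
    if n < 100:
        raise ValidationError(f"chain too short for Geweke diagnostic (n={n})")
    if not 0 < first_fraction < 1 or not 0 < last_fraction < 1:
        raise ValidationError("segment fractions must lie in (0, 1)")
    if first_fraction + last_fraction > 1:
        raise ValidationError("first and last segments must not overlap")
    n1 = int(n * first_fraction)
    n2 = int(n * last_fraction)
    seg1, seg2 = chain[:n1], chain[n - n2 :]
    v1, v2 = _batch_means_variance(seg1), _batch_means_variance(seg2)
    if v1 <= 0 or v2 <= 0:
        raise DegenerateChainError("zero-variance segment; Geweke undefined")
    return float((seg1.mean() - seg2.mean()) / math.sqrt(v1 / n1 + v2 / n2))


def geweke_table(chains: PosteriorChains, **kw) -> pd.DataFrame:
    """Geweke z per top-level parameter, as a one-column DataFrame."""
    rows = {}
    for name in chains.parameter_names:
        c = chains[name]
        try:
            rows[name] = geweke_z(c, **kw)
        except DegenerateChainError:
            rows[name] = math.nan
    return pd.DataFrame({"z": rows})


def summarize_posterior(chain, hdr_levels=(0.68, 0.95)) -> dict:
    """Mean, sd and highest-density regions of a scalar chain.

    HDRs are the shortest empirical intervals holding the stated mass
    (computed with ``arviz.hdi``); the narrower region is nested inside
    the wider one by construction for unimodal draws and clipped into it
    otherwise.
    """
    import arviz as az

    chain = np.asarray(chain, dtype=float)
    if chain.size == 0:
        raise ValidationError("empty chain")
    levels = sorted(hdr_levels)
    out = {"mean": float(chain.mean()), "sd": float(chain.std(ddof=1)) if chain.size > 1 else 0.0}
    hdr: dict[float, tuple[float, float]] = {}
    if np.ptp(chain) == 0.0:
        v = float(chain[0])
        out["hdr"] = {lev: (v, v) for lev in levels}
        return out
    for lev in levels:
        lo, hi = az.hdi(chain, hdi_prob=lev)
        hdr[lev] = (float(lo), float(hi))
    # enforce nesting: clip each interval into the next wider one
    for narrow, wide in zip(levels[:-1], levels[1:]):
        lo_n, hi_n = hdr[narrow]
        lo_w, hi_w = hdr[wide]
        hdr[narrow] = (max(lo_n, lo_w), min(hi_n, hi_w))
    out["hdr"] = hdr
    return out
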