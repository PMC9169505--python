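"""Posterior sampling and convergence diagnostics.

Sampling uses an adaptive Metropolis-within-Gibbs scheme tailored to the
piecewise curve model:

* each 4-vector of fixed-effect coefficients (one curve quantity) is a
  joint random-walk Metropolis block;
* subject-level and occasion-level random effects are updated with
  element-wise Metropolis proposals, exploiting the fact that the
  likelihood factorises across subjects/sessions;
* all variances have conjugate inverse-Gamma full conditionals given the
  current effects and are drawn by Gibbs steps.

Proposal scales adapt towards standard acceptance targets during burn-in
and are frozen afterwards, so the retained chain is a valid Markov chain.
Runs are deterministic given the seed (one independent stream per chain).

The diagnostic battery mirrors standard MCMC practice: the Brooks-Gelman
potential scale reduction factor, Geweke's two-window mean comparison and
the Heidelberger-Welch stationarity/halfwidth test, all built on a common
spectral-density-at-zero estimate (AR fit with AIC order selection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.regression.linear_model import yule_walker

from .data_model import Dataset, PosteriorDraws
from .model_core import (COVARIATE_NAMES, PARAM_NAMES, PriorSpec,
                         RandomEffectsSpec, default_priors, design_row, mu_matrix)
from .preprocess import DEFAULT_SCHEME, DEFAULT_SHIFT, SegmentScheme, transform_dataset


class FitError(RuntimeError):
    """Raised when sampling cannot be initialised or configured."""


@dataclass
class ModelConfig:
    """Model-side configuration: priors, random-effect structure, transform."""

    priors: PriorSpec = field(default_factory=default_priors)
    random_effects: RandomEffectsSpec = field(default_factory=RandomEffectsSpec)
    transient_mode: str = "midpoint"
    shift_constant: float = DEFAULT_SHIFT
    scheme: SegmentScheme = field(default_factory=lambda: DEFAULT_SCHEME)


@dataclass
class FitConfig:
    """Sampler controls. ``iterations`` is the total per chain including
    burn-in; every ``thinning``-th post-burn-in draw is retained."""

    chains: int = 2
    iterations: int = 2000
    burn_in: int = 500
    thinning: int = 1
    seed: int = 0
    initial_step: float = 0.1
    adapt_every: int = 50
    store_random_effects: bool = True

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise FitError("at least one chain required")
        if not (self.iterations > self.burn_in >= 0):
            raise FitError("iterations must exceed burn_in >= 0")
        if self.thinning < 1:
            raise FitError("thinning must be >= 1")


# ---------------------------------------------------------------------------
# internal flattened representation of the data


class _ModelData:
    def __init__(self, dataset: Dataset, config: ModelConfig):
        series = transform_dataset(dataset, config.scheme, config.shift_constant)
        subjects = dataset.subjects
        self.subj_of = {s: i for i, s in enumerate(subjects)}
        self.n_subjects = len(subjects)
        self.n_series = len(series)
        self.Y = np.stack([s.y for s in series])
        self.X = np.stack([design_row(s.treatment, s.start) for s in series])
        self.subj_idx = np.array([self.subj_of[s.subject_id] for s in series])
        self.subjects = subjects


class _ChainState:
    """Mutable sampler state for one chain."""

    def __init__(self, data: _ModelData, config: ModelConfig, rng: np.random.Generator):
        loc, var = config.priors.coefficient_array()
        self.beta = loc + 0.1 * np.sqrt(var) * rng.standard_normal((8, 4))
        self.active = tuple(config.random_effects.active)
        self.gamma = {k: 0.01 * rng.standard_normal(data.n_subjects)
                      for k in self.active}
        self.occ = 0.01 * rng.standard_normal(data.n_series)
        self.sigma2 = 0.5
        self.lam2 = {k: 0.25 for k in self.active}
        self.lam2_occ = 0.25

    def curve_params(self, data: _ModelData) -> tuple[np.ndarray, np.ndarray]:
        """(n_series, 8) curve quantities and length-n_series gammaT."""
        params = data.X @ self.beta.T
        for k in self.active:
            if k == "T":
                continue
            params[:, PARAM_NAMES.index(k)] += self.gamma[k][data.subj_idx]
        if "T" in self.active:
            gammaT = self.gamma["T"][data.subj_idx]
        else:
            gammaT = np.zeros(data.n_series)
        return params, gammaT


def _series_ss(data: _ModelData, mu: np.ndarray) -> np.ndarray:
    """Per-series residual sum of squares."""
    return np.sum((data.Y - mu) ** 2, axis=1)


def _run_chain(data: _ModelData, config: ModelConfig, fit: FitConfig,
               rng: np.random.Generator) -> dict[str, np.ndarray]:
    priors = config.priors
    loc, var = priors.coefficient_array()
    state = None
    for attempt in range(5):
        cand = _ChainState(data, config, rng)
        params, gammaT = cand.curve_params(data)
        mu = mu_matrix(params, gammaT, cand.occ, config.transient_mode)
        if np.all(np.isfinite(mu)):
            state = cand
            break
    if state is None:
        raise FitError("could not find a finite initial log-posterior "
                       "after 5 seeded restarts")
    ss = _series_ss(data, mu)

    step_beta = np.full(8, fit.initial_step)
    step_gamma = {k: fit.initial_step for k in state.active}
    step_occ = fit.initial_step
    acc_beta = np.zeros(8)
    acc_gamma = {k: 0.0 for k in state.active}
    acc_occ = 0.0
    # running moments of each beta block for covariance-adapted proposals
    cov_n = 0
    cov_mean = np.zeros((8, 4))
    cov_m2 = np.zeros((8, 4, 4))
    chol = [None] * 8
    scale_beta = np.ones(8)

    n_keep = (fit.iterations - fit.burn_in + fit.thinning - 1) // fit.thinning
    out: dict[str, np.ndarray] = {}
    for i, p in enumerate(PARAM_NAMES):
        for k, c in enumerate(COVARIATE_NAMES):
            out[f"beta_{p}_{c}"] = np.empty(n_keep)
    out["sigma2"] = np.empty(n_keep)
    for k in state.active:
        out[f"lambda2_{k}"] = np.empty(n_keep)
    out["lambda2_occasion"] = np.empty(n_keep)
    if fit.store_random_effects:
        for k in state.active:
            for s in range(data.n_subjects):
                out[f"gamma_{k}[{data.subjects[s]}]"] = np.empty(n_keep)
        for r in range(data.n_series):
            out[f"gamma_occ[{r}]"] = np.empty(n_keep)

    a0, b0 = priors.precision_shape, priors.precision_rate
    kept = 0
    for it in range(fit.iterations):
        adapting = it < fit.burn_in
        # --- fixed-effect blocks -----------------------------------------
        for pi in range(8):
            prop = state.beta.copy()
            if chol[pi] is not None:
                jump = scale_beta[pi] * (chol[pi] @ rng.standard_normal(4))
            else:
                jump = step_beta[pi] * rng.standard_normal(4)
            prop[pi] = state.beta[pi] + jump
            beta_save = state.beta
            state.beta = prop
            params, gammaT = state.curve_params(data)
            mu_new = mu_matrix(params, gammaT, state.occ, config.transient_mode)
            ss_new = _series_ss(data, mu_new)
            dlp = (-0.5 * (ss_new.sum() - ss.sum()) / state.sigma2
                   + np.sum(-0.5 * (prop[pi] - loc[pi]) ** 2 / var[pi])
                   - np.sum(-0.5 * (beta_save[pi] - loc[pi]) ** 2 / var[pi]))
            if np.isfinite(dlp) and math.log(rng.random()) < dlp:
                mu, ss = mu_new, ss_new
                acc_beta[pi] += 1
            else:
                state.beta = beta_save
        # --- subject random effects (element-wise acceptance) -------------
        for k in state.active:
            g_old = state.gamma[k]
            g_prop = g_old + step_gamma[k] * rng.standard_normal(data.n_subjects)
            state.gamma[k] = g_prop
            params, gammaT = state.curve_params(data)
            mu_new = mu_matrix(params, gammaT, state.occ, config.transient_mode)
            ss_new = _series_ss(data, mu_new)
            d_series = -0.5 * (ss_new - ss) / state.sigma2
            d_subj = np.bincount(data.subj_idx, weights=d_series,
                                 minlength=data.n_subjects)
            d_subj += -0.5 * (g_prop ** 2 - g_old ** 2) / state.lam2[k]
            accept = np.log(rng.random(data.n_subjects)) < d_subj
            state.gamma[k] = np.where(accept, g_prop, g_old)
            if accept.all():
                mu, ss = mu_new, ss_new
            elif accept.any():
                params, gammaT = state.curve_params(data)
                mu = mu_matrix(params, gammaT, state.occ, config.transient_mode)
                ss = _series_ss(data, mu)
            acc_gamma[k] += accept.mean()
        # --- translation moves: trade the intercept against the mean of its
        # subject effects (likelihood-invariant, fixes hierarchical
        # mean-drift mixing); acceptance uses the prior ratio only ---------
        for k in state.active:
            if k == "T":
                continue
            pi = PARAM_NAMES.index(k)
            delta = 0.2 * rng.standard_normal()
            b_old = state.beta[pi, 0]
            g_old = state.gamma[k]
            dlp = (-0.5 * ((b_old + delta - loc[pi, 0]) ** 2
                           - (b_old - loc[pi, 0]) ** 2) / var[pi, 0]
                   - 0.5 * (np.sum((g_old - delta) ** 2)
                            - np.sum(g_old ** 2)) / state.lam2[k])
            if math.log(rng.random()) < dlp:
                state.beta[pi, 0] = b_old + delta
                state.gamma[k] = g_old - delta
        # --- occasion effects (per-series acceptance) ---------------------
        occ_old = state.occ
        occ_prop = occ_old + step_occ * rng.standard_normal(data.n_series)
        d_series = (-0.5 * np.sum((data.Y - (mu - occ_old[:, None]
                                             + occ_prop[:, None])) ** 2, axis=1)
                    + 0.5 * ss) / state.sigma2
        d_series += -0.5 * (occ_prop ** 2 - occ_old ** 2) / state.lam2_occ
        accept = np.log(rng.random(data.n_series)) < d_series
        state.occ = np.where(accept, occ_prop, occ_old)
        mu = mu + (state.occ - occ_old)[:, None]
        ss = _series_ss(data, mu)
        acc_occ += accept.mean()
        # --- Gibbs steps for the variances --------------------------------
        n_obs = data.Y.size
        state.sigma2 = 1.0 / rng.gamma(a0 + 0.5 * n_obs,
                                       1.0 / (b0 + 0.5 * ss.sum()))
        for k in state.active:
            g = state.gamma[k]
            state.lam2[k] = 1.0 / rng.gamma(a0 + 0.5 * data.n_subjects,
                                            1.0 / (b0 + 0.5 * np.sum(g ** 2)))
        state.lam2_occ = 1.0 / rng.gamma(a0 + 0.5 * data.n_series,
                                         1.0 / (b0 + 0.5 * np.sum(state.occ ** 2)))
        # --- adaptation ----------------------------------------------------
        if adapting:
            # running covariance of the beta blocks (Haario-style proposals)
            cov_n += 1
            delta = state.beta - cov_mean
            cov_mean += delta / cov_n
            cov_m2 += np.einsum("pi,pj->pij", delta, state.beta - cov_mean)
        if adapting and (it + 1) % fit.adapt_every == 0:
            rates = acc_beta / fit.adapt_every
            step_beta *= np.where(rates > 0.3, 1.25, 0.8)
            scale_beta *= np.where(rates > 0.25, 1.15, 0.85)
            acc_beta[:] = 0
            if cov_n >= 200:
                cov = cov_m2 / (cov_n - 1)
                for pi in range(8):
                    try:
                        chol[pi] = np.linalg.cholesky(
                            (2.38 ** 2 / 4.0) * cov[pi] + 1e-8 * np.eye(4))
                    except np.linalg.LinAlgError:  # pragma: no cover
                        chol[pi] = None
            for k in state.active:
                rate = acc_gamma[k] / fit.adapt_every
                step_gamma[k] *= 1.25 if rate > 0.4 else 0.8
                acc_gamma[k] = 0.0
            step_occ *= 1.25 if acc_occ / fit.adapt_every > 0.4 else 0.8
            acc_occ = 0.0
        # --- storage --------------------------------------------------------
        if it >= fit.burn_in and (it - fit.burn_in) % fit.thinning == 0:
            for i, p in enumerate(PARAM_NAMES):
                for k, c in enumerate(COVARIATE_NAMES):
                    out[f"beta_{p}_{c}"][kept] = state.beta[i, k]
            out["sigma2"][kept] = state.sigma2
            for k in state.active:
                out[f"lambda2_{k}"][kept] = state.lam2[k]
            out["lambda2_occasion"][kept] = state.lam2_occ
            if fit.store_random_effects:
                for k in state.active:
                    for s in range(data.n_subjects):
                        out[f"gamma_{k}[{data.subjects[s]}]"][kept] = state.gamma[k][s]
                for r in range(data.n_series):
                    out[f"gamma_occ[{r}]"][kept] = state.occ[r]
            kept += 1
    return out


def fit_mcmc(dataset: Dataset, model_config: ModelConfig | None = None,
             fit_config: FitConfig | None = None) -> PosteriorDraws:
    """Sample the posterior of all model unknowns.

    Deterministic given ``fit_config.seed``; chains use independent
    spawned streams.  Per-chain traces are retained for diagnostics.
    """
    if len(dataset.series) == 0:
        raise FitError("dataset contains no series")
    model_config = model_config or ModelConfig()
    fit_config = fit_config or FitConfig()
    data = _ModelData(dataset, model_config)
    seeds = np.random.SeedSequence(fit_config.seed).spawn(fit_config.chains)
    chains = [_run_chain(data, model_config, fit_config,
                         np.random.default_rng(s)) for s in seeds]
    draws = {p: np.stack([c[p] for c in chains]) for p in chains[0]}
    meta = {
        "seed": fit_config.seed,
        "iterations": fit_config.iterations,
        "burn_in": fit_config.burn_in,
        "thinning": fit_config.thinning,
        "chains": fit_config.chains,
        "transient_mode": model_config.transient_mode,
        "active_random_effects": list(model_config.random_effects.active),
    }
    return PosteriorDraws(draws, meta)


# ---------------------------------------------------------------------------
# Spectral density at zero (shared by the diagnostics)


def spectrum0(chain: np.ndarray, max_order: int | None = None) -> float:
    """Spectral density of the chain at frequency zero.

    Fits autoregressive models by Yule-Walker for orders ``0..max_order``,
    selects the order by AIC, and returns ``sigma2 / (1 - sum(phi))**2``.
    A constant chain returns 0.
    """
    x = np.asarray(chain, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("chain too short for spectral estimation")
    if np.allclose(x, x[0]):
        return 0.0
    if max_order is None:
        max_order = min(30, n // 10, n - 2)
    x = x - x.mean()
    best_aic, best = np.inf, None
    var0 = float(np.var(x))
    for order in range(0, max_order + 1):
        if order == 0:
            sigma2, rho = var0, np.array([])
        else:
            try:
                rho, sigma = yule_walker(x, order=order, method="mle")
            except np.linalg.LinAlgError:  # pragma: no cover
                continue
            sigma2 = float(sigma) ** 2
        if sigma2 <= 0:
            continue
        aic = n * math.log(sigma2) + 2.0 * order
        if aic < best_aic:
            best_aic = aic
            best = (sigma2, rho)
    sigma2, rho = best
    denom = (1.0 - float(np.sum(rho))) ** 2
    return sigma2 / denom if denom > 0 else np.inf


# ---------------------------------------------------------------------------
# Gelman-Rubin


def gelman_rubin(chains: np.ndarray) -> float:
    """Brooks-Gelman potential scale reduction factor.

    ``chains`` is (m, n) with m >= 2 parallel chains of equal length.
    Exact duplicate chains give sqrt((n-1)/n) < 1.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("gelman_rubin requires >= 2 chains of equal length")
    m, n = chains.shape
    W = float(np.mean(np.var(chains, axis=1, ddof=1)))
    B_over_n = float(np.var(np.mean(chains, axis=1), ddof=1))
    if W == 0:
        return 1.0 if B_over_n == 0 else np.inf
    v_hat = (n - 1) / n * W + B_over_n
    return math.sqrt(v_hat / W)


# ---------------------------------------------------------------------------
# Geweke


def geweke(chain: np.ndarray, first_fraction: float = 0.1,
           last_fraction: float = 0.5) -> tuple[float, float]:
    """Geweke's convergence z-score and two-sided p-value.

    Compares the mean of the first ``first_fraction`` of the chain with the
    mean of the last ``last_fraction``, with variances taken from the
    spectral density at zero of each window.
    """
    if first_fraction + last_fraction > 1.0:
        raise ValueError("Geweke windows overlap")
    x = np.asarray(chain, dtype=float)
    n = x.size
    n1 = max(int(first_fraction * n), 1)
    n2 = max(int(last_fraction * n), 1)
    a, b = x[:n1], x[n - n2:]
    if n1 < 5 or n2 < 5:
        raise ValueError("chain too short for the Geweke windows")
    s1, s2 = spectrum0(a), spectrum0(b)
    denom = math.sqrt(s1 / n1 + s2 / n2)
    z = 0.0 if denom == 0 else (a.mean() - b.mean()) / denom
    p = 2.0 * (1.0 - stats.norm.cdf(abs(z)))
    return z, p


# ---------------------------------------------------------------------------
# Heidelberger-Welch


def _cvm_sf(x: float) -> float:
    """Survival function of the asymptotic Cramér-von Mises distribution."""
    if x <= 0:
        return 1.0
    if x > 1.0:
        # the 12-term series loses accuracy far in the tail, where the
        # survival probability is below ~5e-4 anyway
        return 0.0
    total = 0.0
    for j in range(12):
        u = (4 * j + 1) ** 2 / (16.0 * x)
        if u > 700:
            continue
        term = (special.gamma(j + 0.5) * math.sqrt(4 * j + 1)
                / (special.gamma(0.5) * special.factorial(j))
                * math.exp(-u) * special.kv(0.25, u))
        total += term
    cdf = total / (math.pi * math.sqrt(x))
    return float(min(max(1.0 - cdf, 0.0), 1.0))


@dataclass
class HeidelbergerWelchResult:
    stationarity_p: float
    stationary: bool
    n_discarded: int
    halfwidth: float
    halfwidth_ratio: float
    halfwidth_pass: bool
    mean: float


def heidelberger_welch(chain: np.ndarray, alpha: float = 0.05,
                       eps: float = 0.1,
                       level: float = 0.95) -> HeidelbergerWelchResult:
    """Heidelberger-Welch stationarity and halfwidth tests.

    The Cramér-von Mises statistic of the standardised cumulative-sum
    (Brownian bridge) process is tested against its asymptotic
    distribution, normalising with the spectral density at zero estimated
    from the *second half* of the retained chain (so an early mean shift
    cannot mask itself); on failure the initial 10% of the chain is
    discarded and the test repeated while at least 60% of the chain
    remains.  The halfwidth test compares the ``level`` confidence
    halfwidth of the retained mean against ``eps`` times the mean.
    """
    x = np.asarray(chain, dtype=float)
    if x.size < 100:
        raise ValueError("heidelberger_welch requires a chain of length >= 100")
    n0 = x.size
    discarded = 0
    p_value = 0.0
    stationary = False
    retained = x
    for k in range(5):  # discard 0%..40% in steps of 10%
        start = int(0.1 * k * n0)
        retained = x[start:]
        n = retained.size
        s0 = spectrum0(retained[n // 2:])
        if s0 == 0:
            if np.allclose(retained, retained[0]):  # constant: stationary
                p_value, stationary, discarded = 1.0, True, start
                break
            discarded = start  # constant tail after a shift: keep discarding
            p_value = 0.0
            continue
        csum = np.cumsum(retained - retained.mean())
        bridge = csum / math.sqrt(n * s0)
        cvm = float(np.sum(bridge ** 2)) / n
        p_value = _cvm_sf(cvm)
        if p_value > alpha:
            stationary, discarded = True, start
            break
        discarded = start
    mean = float(retained.mean())
    s0 = spectrum0(retained)
    z = stats.norm.ppf(0.5 + level / 2.0)
    halfwidth = z * math.sqrt(s0 / retained.size)
    ratio = 0.0 if halfwidth == 0 else (abs(halfwidth / mean) if mean != 0 else np.inf)
    return HeidelbergerWelchResult(
        stationarity_p=p_value, stationary=stationary, n_discarded=discarded,
        halfwidth=halfwidth, halfwidth_ratio=ratio,
        halfwidth_pass=bool(ratio <= eps), mean=mean)


# ---------------------------------------------------------------------------
# Posterior summaries


@dataclass
class ParameterSummary:
    name: str
    mean: float
    sd: float
    ci_lower: float
    ci_upper: float
    naive_se: float
    timeseries_se: float
    gelman_rubin: float
    hw_p: float
    geweke_p: float


def summarize(draws: PosteriorDraws, level: float = 0.95,
              priors: PriorSpec | None = None) -> pd.DataFrame:
    """Per-parameter posterior summaries in the standard report layout.

    Columns: prior (when available), posterior mean and SD, equal-tailed
    credible bounds, naive and time-series (autocorrelation-adjusted)
    standard errors, and the three convergence diagnostics.  Geweke and
    Heidelberger-Welch are computed per chain and the smallest p-value is
    reported (the most conservative flag).
    """
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    prior_label = {}
    if priors is not None:
        for name, (loc, var) in priors.coefficients.items():
            prior_label[name] = f"N({loc:g},{var:g})"
    for p in draws.parameters:
        mat = draws.draws[p]
        flat = mat.reshape(-1)
        mean, sd = float(flat.mean()), float(flat.std(ddof=1))
        n = flat.size
        try:
            s0 = float(np.mean([spectrum0(c) for c in mat]))
        except ValueError:  # chains too short for an AR fit: treat as iid
            s0 = sd ** 2
        gr = gelman_rubin(mat) if mat.shape[0] >= 2 else np.nan
        try:
            gw = min(geweke(c)[1] for c in mat)
        except ValueError:
            gw = np.nan
        try:
            hw = min(heidelberger_welch(c).stationarity_p for c in mat)
        except ValueError:
            hw = np.nan
        label = prior_label.get(p, "GA(0.001,0.001)" if p.startswith(
            ("sigma2", "lambda2")) else "—")
        rows.append({
            "Parameter": p,
            "Prior": label,
            "Mean": mean,
            "SD": sd,
            f"{lo_q * 100:.1f}%": float(np.quantile(flat, lo_q)),
            f"{hi_q * 100:.1f}%": float(np.quantile(flat, hi_q)),
            "Naive SE": sd / math.sqrt(n),
            "Time-series SE": math.sqrt(s0 / n),
            "GR statistic": gr,
            "HW p-value": hw,
            "GW p-value": gw,
        })
    return pd.DataFrame(rows).set_index("Parameter")
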