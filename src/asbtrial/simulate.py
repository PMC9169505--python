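"""Synthetic Williams-crossover TLQ data from the generative curve model.

The generator draws subject- and occasion-level random effects, evaluates
the piecewise mean curve on the transformed scale, adds Gaussian noise,
and then *inverts* the preprocessing chain segment by segment to produce
integer 1-10 Likert trajectories (rounding half away from zero, clamping
to the scale ends).  Defaults emulate the pilot study conditions: six
subjects, three sessions in Williams order, baselines drawn uniformly from
the mid-scale range 4-8, and curve parameters centred at the prior
locations of the fitted model.

Also provides the parameter-recovery and design-operating-characteristic
experiment harnesses used to validate the fitting machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import (Dataset, RawTLQSeries, Treatment,
                         assign_williams_sequences, LIKERT_MIN, LIKERT_MAX)
from .model_core import (PARAM_NAMES, FixedEffects, RandomEffectsSpec,
                         design_row, mu_matrix)
from .preprocess import (DEFAULT_SCHEME, DEFAULT_SHIFT, SegmentScheme,
                         invert_transform)
from . import derived_quantities, inference, samplesize_adaptive


def default_truth_beta() -> np.ndarray:
    """Plausible generating coefficients emulating the pilot conditions: a
    flat PRE at the shifted reference, online means rising from 5 toward
    5.8 under the active control (a gain of 0.8, i.e. a minimum clinical
    efficacy near 0.4), a small residual carry-over, small treatment
    effects on the online ceiling and inflection, no baseline effect."""
    beta = np.zeros((8, 4))
    intercepts = {"a": 5.0, "b": 0.0, "c": 5.8, "d": 2.0,
                  "e": 11.0, "f": 5.0, "g": 5.3, "h": 0.3}
    for i, p in enumerate(PARAM_NAMES):
        beta[i, 0] = intercepts[p]
    beta[PARAM_NAMES.index("c"), 1] = 0.2   # SP effect on the online maximum
    beta[PARAM_NAMES.index("c"), 2] = 0.5   # tP effect on the online maximum
    beta[PARAM_NAMES.index("e"), 2] = -0.5  # tP reaches inflection earlier
    return beta


@dataclass
class TruthSpec:
    """Generating parameter values for the simulator."""

    beta: np.ndarray = field(default_factory=default_truth_beta)
    random_effects: RandomEffectsSpec = field(default_factory=lambda: RandomEffectsSpec(
        active=("c", "e", "f", "T"),
        lambda2={"c": 0.1, "e": 0.1, "f": 0.1, "T": 0.05},
        lambda2_occasion=0.05,
        sigma2=0.2,
    ))
    shift_constant: float = DEFAULT_SHIFT
    start_values: tuple = (4, 5, 6, 7, 8)
    transient_mode: str = "midpoint"
    clamp_warn_fraction: float = 0.2
    #: round reconstructed raw values to the integer Likert scale (real
    #: TLQ data are integers; disable to study the idealised model)
    round_to_likert: bool = True

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (8, 4):
            raise ValueError("beta must be 8x4")

    def fixed_effects(self) -> FixedEffects:
        return FixedEffects(self.beta.copy())


def simulate_dataset(n_subjects: int, truth: TruthSpec | None = None,
                     seed: int = 0,
                     scheme: SegmentScheme = DEFAULT_SCHEME) -> Dataset:
    """Generate a Williams-crossover dataset of 21-point Likert series.

    Deterministic given ``seed``.  A warning is recorded when more than
    ``truth.clamp_warn_fraction`` of the raw values land on the scale
    boundary after clamping.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    truth = truth or TruthSpec()
    rng = np.random.default_rng(seed)
    sequences = assign_williams_sequences(n_subjects, seed=int(rng.integers(2 ** 31)))
    spec = truth.random_effects
    gamma = {k: (np.sqrt(spec.lambda2.get(k, 0.0))
                 * rng.standard_normal(n_subjects))
             for k in spec.active}
    series: list[RawTLQSeries] = []
    clamped = 0
    total = 0
    for i in range(n_subjects):
        subject = f"S{i + 1:03d}"
        start = int(rng.choice(truth.start_values))
        for session, trt in enumerate(sequences[i], start=1):
            x = design_row(trt, start)
            params = (truth.beta @ x)[None, :].copy()
            for k in spec.active:
                if k != "T":
                    params[0, PARAM_NAMES.index(k)] += gamma[k][i]
            gammaT = np.array([gamma["T"][i]]) if "T" in spec.active else np.zeros(1)
            occ = np.sqrt(spec.lambda2_occasion) * rng.standard_normal(1)
            mu = mu_matrix(params, gammaT, occ, truth.transient_mode)[0]
            y = mu + np.sqrt(spec.sigma2) * rng.standard_normal(mu.size)
            raw = invert_transform(y, start, scheme, truth.shift_constant)
            if truth.round_to_likert:
                raw = np.sign(raw) * np.floor(np.abs(raw) + 0.5)  # half away from zero
            clipped = np.clip(raw, LIKERT_MIN, LIKERT_MAX)
            clamped += int(np.sum(clipped != raw))
            total += clipped.size
            series.append(RawTLQSeries(subject, session, trt, clipped.tolist()))
    if total and clamped / total > truth.clamp_warn_fraction:
        warnings.warn(
            f"{clamped / total:.0%} of simulated raw values hit the Likert "
            "boundary; generating parameters may be unrealistic",
            stacklevel=2)
    seqs = {f"S{i + 1:03d}": tuple(sequences[i]) for i in range(n_subjects)}
    return Dataset(series, seqs)


# ---------------------------------------------------------------------------
# parameter recovery


def parameter_recovery_experiment(reps: int, n_subjects: int,
                                  truth: TruthSpec | None = None,
                                  model_config: "inference.ModelConfig | None" = None,
                                  fit_config: "inference.FitConfig | None" = None,
                                  seed: int = 0,
                                  level: float = 0.90) -> pd.DataFrame:
    """Simulate -> fit -> score credible-interval coverage, per replicate.

    Returns one row per (replicate, fixed-effect coefficient) with the
    true value, posterior mean, bias, posterior sd and whether the
    equal-tailed ``level`` interval covered the truth.  Fit failures are
    counted (column ``failed``) rather than fatal.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    truth = truth or TruthSpec()
    model_config = model_config or inference.ModelConfig(
        random_effects=replace(truth.random_effects))
    fit_config = fit_config or inference.FitConfig()
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    root = np.random.SeedSequence(seed)
    for rep, child in enumerate(root.spawn(reps)):
        sim_seed, fit_seed = [int(s) % (2 ** 31) for s in child.generate_state(2)]
        dataset = simulate_dataset(n_subjects, truth, seed=sim_seed)
        cfg = replace(fit_config, seed=fit_seed)
        try:
            draws = inference.fit_mcmc(dataset, model_config, cfg)
        except inference.FitError:
            rows.append({"replicate": rep, "parameter": None, "failed": True})
            continue
        from .model_core import COVARIATE_NAMES
        for i, p in enumerate(PARAM_NAMES):
            for k, cov in enumerate(COVARIATE_NAMES):
                name = f"beta_{p}_{cov}"
                flat = draws.flat(name)
                true_val = truth.beta[i, k]
                lo, hi = np.quantile(flat, [lo_q, hi_q])
                rows.append({
                    "replicate": rep, "parameter": name, "failed": False,
                    "truth": true_val, "posterior_mean": float(flat.mean()),
                    "bias": float(flat.mean() - true_val),
                    "posterior_sd": float(flat.std(ddof=1)),
                    "ci_lower": float(lo), "ci_upper": float(hi),
                    "covered": bool(lo <= true_val <= hi),
                })
    return pd.DataFrame(rows)


def coverage_table(recovery: pd.DataFrame) -> pd.DataFrame:
    ok = recovery[~recovery["failed"]]
    return (ok.groupby("parameter")
              .agg(coverage=("covered", "mean"), mean_bias=("bias", "mean"),
                   mean_sd=("posterior_sd", "mean"), n=("covered", "size")))


# ---------------------------------------------------------------------------
# design operating characteristics


def design_operating_characteristics(scenarios: dict, reps: int = 10,
                                     n_subjects: int = 6,
                                     fit_config: "inference.FitConfig | None" = None,
                                     delta: float = 0.4,
                                     credible: float = 0.95,
                                     seed: int = 0) -> pd.DataFrame:
    """Simulate full interim runs through the decision engine.

    ``scenarios`` maps a name to a :class:`TruthSpec`.  Each replicate
    simulates a cohort, fits the model, evaluates the H1/H2 posterior
    probabilities over the online period and records the engine's action.
    Reports superiority-declaration and stop-for-futility rates per
    scenario.
    """
    fit_config = fit_config or inference.FitConfig(
        chains=2, iterations=800, burn_in=300, store_random_effects=False)
    rows = []
    root = np.random.SeedSequence(seed)
    online = list(range(7, 17))
    for name, truth in scenarios.items():
        children = root.spawn(reps)
        for rep, child in enumerate(children):
            sim_seed, fit_seed = [int(s) % (2 ** 31) for s in child.generate_state(2)]
            dataset = simulate_dataset(n_subjects, truth, seed=sim_seed)
            cfg = replace(fit_config, seed=fit_seed)
            model_config = inference.ModelConfig(
                random_effects=replace(truth.random_effects))
            try:
                draws = inference.fit_mcmc(dataset, model_config, cfg)
            except inference.FitError:
                rows.append({"scenario": name, "replicate": rep, "failed": True})
                continue
            h2 = derived_quantities.treatment_contrast(
                draws, (Treatment.TP, Treatment.PEI), online, delta)
            h1 = derived_quantities.treatment_contrast(
                draws, (Treatment.SP, Treatment.PEI), online, delta)
            state = samplesize_adaptive.AdaptiveState(
                delta_status=samplesize_adaptive.DeltaStatus.VALID, delta=delta)
            decision = samplesize_adaptive.adaptive_decision(
                state, h1["p_equivalent"], h2["p_superior"],
                dose_prob=0.5, credible=credible)
            rows.append({
                "scenario": name, "replicate": rep, "failed": False,
                "p_h1": h1["p_equivalent"], "p_h2": h2["p_superior"],
                "action": decision["action"],
                "declared_superior": h2["p_superior"] >= credible,
                "stopped_futility": (1 - h2["p_superior"]) >= credible,
            })
    df = pd.DataFrame(rows)
    return df


def oc_summary(oc: pd.DataFrame) -> pd.DataFrame:
    ok = oc[~oc["failed"]]
    return (ok.groupby("scenario")
              .agg(superiority_rate=("declared_superior", "mean"),
                   futility_rate=("stopped_futility", "mean"),
                   n=("declared_superior", "size")))
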