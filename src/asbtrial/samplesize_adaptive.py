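"""Sample-size calculators, uncertainty reduction and the adaptive engine.

Three conventional calculators back the interim analyses of the seamless
design, each exposed behind a named default formula:

* ``n_cv_difference`` (N3) — detect a change in coefficient of variation
  between the PRE and ONLINE blocks of the active control:
  n = (z_{1-alpha/2} + z_{1-beta})^2 (cv1^2 + cv2^2) / (cv2 - cv1)^2.
* ``n_repeated_measures`` (N4) — detect a mean difference delta with m
  correlated repeated measures (intra-class correlation rho):
  n = groups (z_{1-alpha/2} + z_{1-beta})^2 sigma2 (1 + (m-1) rho) / (m delta^2).
* ``n_dose_contrast`` (N5) — detect a nonzero linear contrast of the
  ONLINE time-point means:
  n = (z_{1-alpha/2} + z_{1-beta})^2 sigma2 sum(c_j^2) / (sum c_j mu_j)^2.

``posterior_sample_size`` lifts any of these from point inputs to a
posterior distribution of n by evaluating the formula per posterior draw,
yielding a sequential sampling plan (interim sizes at ascending quantiles).

``uncertainty_reduction`` quantifies information gained between interims:
if the expected values of two successive posteriors are equivalent (normal
approximation Bayes factor), UR = (1 - L_curr/L_prev) x 100% where L are
the credible-interval lengths (or, alternatively, posterior coefficients
of variation).

The decision engine encodes the trial roadmap: a delta estimate moves
through processed -> valid states, and with a valid delta the H1 (sham+PEI
similar to PEI), H2 (tDCS+PEI superior to PEI) and Dose hypotheses drive
adaptation: eliminating the active-control session, stopping for futility,
or fixing the minimum/maximum effective dose and moving to the
multisession confirmatory study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# z-quantile helpers


def _z_alpha(alpha: float, sidedness: str) -> float:
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    if sidedness == "two-sided":
        return stats.norm.ppf(1 - alpha / 2)
    if sidedness == "one-sided":
        return stats.norm.ppf(1 - alpha)
    raise ValueError(f"unknown sidedness {sidedness!r}")


def _z_power(power: float) -> float:
    if not 0 < power < 1:
        raise ValueError("power must be in (0,1)")
    return stats.norm.ppf(power)


@dataclass
class SampleSizeResult:
    n: int
    formula: str
    inputs: dict
    n_raw: float
    distribution: np.ndarray | None = None
    quantiles: dict | None = None
    sequential_plan: list | None = None
    excluded_fraction: float = 0.0


def icc(sigma2_subject: float, sigma2_residual: float) -> float:
    """Intra-class correlation rho = sigma0^2 / (sigma0^2 + sigma^2) of
    repeated measures sharing a subject-level random intercept."""
    if sigma2_subject < 0 or sigma2_residual <= 0:
        raise ValueError("variance components must be positive")
    return sigma2_subject / (sigma2_subject + sigma2_residual)


# ---------------------------------------------------------------------------
# conventional calculators


def n_cv_difference(cv1: float, cv2: float, alpha: float = 0.05,
                    power: float = 0.80,
                    sidedness: str = "two-sided") -> SampleSizeResult:
    """N3: sample size to detect a coefficient-of-variation difference."""
    if cv1 <= 0 or cv2 <= 0:
        raise ValueError("CVs must be > 0")
    if cv1 == cv2:
        raise ValueError("equal CVs give an infinite sample size")
    z = _z_alpha(alpha, sidedness) + _z_power(power)
    n_raw = z ** 2 * (cv1 ** 2 + cv2 ** 2) / (cv2 - cv1) ** 2
    return SampleSizeResult(math.ceil(n_raw), "cv_difference",
                            dict(cv1=cv1, cv2=cv2, alpha=alpha, power=power,
                                 sidedness=sidedness), n_raw)


def n_repeated_measures(sigma2_total: float, icc: float, m: int, delta: float,
                        alpha: float = 0.05, power: float = 0.80,
                        groups: int = 2,
                        sidedness: str = "two-sided") -> SampleSizeResult:
    """N4: repeated-measures mean difference with intra-class correlation."""
    if not 0 <= icc < 1:
        raise ValueError("icc must lie in [0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if groups not in (1, 2):
        raise ValueError("groups must be 1 or 2")
    z = _z_alpha(alpha, sidedness) + _z_power(power)
    n_raw = groups * z ** 2 * sigma2_total * (1 + (m - 1) * icc) / (m * delta ** 2)
    return SampleSizeResult(math.ceil(n_raw), "repeated_measures",
                            dict(sigma2_total=sigma2_total, icc=icc, m=m,
                                 delta=delta, alpha=alpha, power=power,
                                 groups=groups, sidedness=sidedness), n_raw)


def n_dose_contrast(means, contrasts, sigma2: float, alpha: float = 0.05,
                    power: float = 0.80,
                    sidedness: str = "two-sided") -> SampleSizeResult:
    """N5: detect a nonzero linear contrast of the online time-point means."""
    mu = np.asarray(means, dtype=float)
    c = np.asarray(contrasts, dtype=float)
    if mu.shape != c.shape:
        raise ValueError("means and contrasts must have the same length")
    if abs(c.sum()) > 1e-8 * max(1.0, np.abs(c).max()):
        raise ValueError("contrasts must sum to 0")
    effect = float(c @ mu)
    if effect == 0:
        raise ValueError("contrast of the means is zero; n undefined")
    z = _z_alpha(alpha, sidedness) + _z_power(power)
    n_raw = z ** 2 * sigma2 * float(c @ c) / effect ** 2
    return SampleSizeResult(math.ceil(n_raw), "dose_contrast",
                            dict(sigma2=sigma2, alpha=alpha, power=power,
                                 sidedness=sidedness), n_raw)


FORMULAS = {
    "cv_difference": n_cv_difference,
    "repeated_measures": n_repeated_measures,
    "dose_contrast": n_dose_contrast,
}


def samplesize_grid(formula: str, powers=(0.75, 0.80, 0.90, 0.99),
                    alphas=(0.01, 0.05, 0.10), **inputs):
    """Table of n over a (power, alpha) grid, mirroring the pilot report."""
    import pandas as pd

    fn = FORMULAS[formula]
    rows = {}
    for pw in powers:
        rows[f"{pw * 100:g}%"] = {
            f"{al * 100:g}%": fn(alpha=al, power=pw, **inputs).n for al in alphas}
    df = pd.DataFrame(rows).T
    df.index.name = "Power"
    df.columns.name = "Significance"
    return df


# ---------------------------------------------------------------------------
# posterior-distribution sample sizes


def posterior_sample_size(draw_inputs: dict, formula: str,
                          quantile_grid=(0.25, 0.50, 0.75, 0.90),
                          **fixed_inputs) -> SampleSizeResult:
    """Evaluate a calculator per posterior draw.

    ``draw_inputs`` maps formula argument names to arrays of equal length
    (one value per posterior draw); ``fixed_inputs`` supplies the scalar
    arguments.  Draws violating the formula preconditions are excluded and
    the exclusion fraction reported.  The sequential plan is the set of
    interim sizes at the requested quantiles (nondecreasing by
    construction).
    """
    fn = FORMULAS[formula]
    names = list(draw_inputs)
    arrays = [np.asarray(draw_inputs[k], dtype=float) for k in names]
    n_draws = arrays[0].size
    if any(a.size != n_draws for a in arrays):
        raise ValueError("all draw inputs must have equal length")
    ns = np.empty(n_draws)
    excluded = 0
    for i in range(n_draws):
        kw = {k: a[i] for k, a in zip(names, arrays)}
        try:
            ns[i] = fn(**kw, **fixed_inputs).n
        except ValueError:
            ns[i] = np.nan
            excluded += 1
    valid = ns[~np.isnan(ns)]
    if valid.size == 0:
        raise ValueError("every draw violated the formula preconditions")
    qs = {q: float(np.quantile(valid, q)) for q in quantile_grid}
    plan = [int(math.ceil(qs[q])) for q in sorted(qs)]
    point = int(np.median(valid))
    return SampleSizeResult(point, formula, dict(fixed_inputs),
                            float(np.median(valid)), distribution=valid,
                            quantiles=qs, sequential_plan=plan,
                            excluded_fraction=excluded / n_draws)


# ---------------------------------------------------------------------------
# uncertainty reduction between interims


def _normal_bf01(draws_prev: np.ndarray, draws_curr: np.ndarray,
                 prior_scale_ratio: float = 10.0) -> float:
    """Normal-approximation Bayes factor for 'the two expected values are
    equal' against a diffuse alternative on the mean difference.

    The difference of posterior means is treated as normal with variance
    sd1^2 + sd2^2; under the alternative the difference has prior scale
    ``prior_scale_ratio`` times that.  BF01 > 1 favours equivalence.
    """
    m1, m2 = draws_prev.mean(), draws_curr.mean()
    s2 = draws_prev.var(ddof=1) + draws_curr.var(ddof=1)
    if s2 == 0:
        return np.inf if m1 == m2 else 0.0
    tau2 = prior_scale_ratio ** 2 * s2
    d = m1 - m2
    log_bf = (0.5 * math.log((s2 + tau2) / s2)
              - 0.5 * d ** 2 * (1.0 / s2 - 1.0 / (s2 + tau2)))
    return math.exp(log_bf)


def uncertainty_reduction(draws_prev, draws_curr, level: float = 0.95,
                          bf_threshold: float = 3.0,
                          prior_scale_ratio: float = 10.0,
                          mode: str = "interval") -> dict:
    """UR = (1 - R) x 100% between two successive posteriors.

    Step 1 checks equivalence of expected values with a
    normal-approximation Bayes factor (equivalent when BF01 exceeds
    ``bf_threshold``); step 2 measures equal-tailed interval lengths at
    ``level`` (or posterior coefficients of variation with
    ``mode="cv"``); step 3 forms R = L_curr / L_prev.
    """
    a = np.asarray(draws_prev, dtype=float)
    b = np.asarray(draws_curr, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both draw sets must be non-empty")
    bf01 = _normal_bf01(a, b, prior_scale_ratio)
    if mode == "interval":
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        l_prev = float(np.quantile(a, hi) - np.quantile(a, lo))
        l_curr = float(np.quantile(b, hi) - np.quantile(b, lo))
    elif mode == "cv":
        l_prev = float(a.std(ddof=1) / abs(a.mean()))
        l_curr = float(b.std(ddof=1) / abs(b.mean()))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if l_prev == 0:
        raise ValueError("previous-interim interval length is zero; R undefined")
    r = l_curr / l_prev
    return {"equivalent": bool(bf01 > bf_threshold), "bf01": float(bf01),
            "L_prev": l_prev, "L_curr": l_curr, "R": float(r),
            "UR": float((1.0 - r) * 100.0)}


# ---------------------------------------------------------------------------
# adaptive state machine


class DeltaStatus(str, Enum):
    PROCESSED_UNCERTAIN = "processed_uncertain"
    PROCESSED_CREDIBLE = "processed_credible"
    VALID = "valid"


class Stage(str, Enum):
    EXPLORATORY = "exploratory"
    CONFIRMATORY = "confirmatory"


@dataclass
class AdaptiveState:
    """The trial's processed-delta status and decision history."""

    stage: Stage = Stage.EXPLORATORY
    delta_status: DeltaStatus = DeltaStatus.PROCESSED_UNCERTAIN
    delta: float | None = None
    interim: str = "N3"
    log: list = field(default_factory=list)

    def record(self, event: str) -> None:
        self.log.append(event)


def _interval_length(draws: np.ndarray, level: float = 0.95) -> float:
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    return float(np.quantile(draws, hi) - np.quantile(draws, lo))


def processed_delta_update(state: AdaptiveState, prev_delta_draws,
                           new_delta_draws, margin_fraction: float = 0.5,
                           level: float = 0.95, bf_threshold: float = 3.0,
                           prior_scale_ratio: float = 10.0) -> AdaptiveState:
    """Advance the delta-confirmation stage with a new interim posterior.

    The new delta posterior is *within the credibility margin* when its
    equal-tailed interval length at ``level`` is at most
    ``margin_fraction`` times the posterior mean delta.  Three outcomes:

    1. not within the margin -> the anterior delta is retained and
       recruitment continues with N3 interims;
    2. within the margin and the means differ (Bayes factor against
       equivalence) -> the new delta replaces the anterior one, downstream
       margins/sample sizes re-adapt, N3 interims continue;
    3. within the margin and the means are equivalent -> delta becomes
       valid, the confirmation stage ends, hypothesis interims begin.
    """
    prev = np.asarray(prev_delta_draws, dtype=float)
    new = np.asarray(new_delta_draws, dtype=float)
    mean_new = float(new.mean())
    within = (mean_new > 0
              and _interval_length(new, level) <= margin_fraction * mean_new)
    bf01 = _normal_bf01(prev, new, prior_scale_ratio)
    if not within:
        state.delta = float(prev.mean()) if state.delta is None else state.delta
        state.delta_status = DeltaStatus.PROCESSED_UNCERTAIN
        state.interim = "N3"
        state.record("delta posterior too wide; anterior delta retained (N3)")
    elif bf01 <= bf_threshold:  # significantly different, but precise
        state.delta = mean_new
        state.delta_status = DeltaStatus.PROCESSED_CREDIBLE
        state.interim = "N3"
        state.stage = Stage.EXPLORATORY
        state.record("delta replaced; margins and sample sizes re-adapted (N3)")
    else:
        state.delta = float(prev.mean()) if state.delta is None else state.delta
        state.delta_status = DeltaStatus.VALID
        state.stage = Stage.CONFIRMATORY
        state.record("delta validated; confirmation stage ends")
    return state


def adaptive_decision(state: AdaptiveState, h1_prob: float, h2_prob: float,
                      dose_prob: float | None = None,
                      credible: float = 0.95) -> dict:
    """Map interim posterior probabilities to the roadmap action.

    ``h1_prob`` — P(SP is equivalent to PEI within delta);
    ``h2_prob`` — P(tP exceeds PEI by more than delta);
    ``dose_prob`` — P(a dose-response relationship holds), required once
    H2 is credible.  A pure function of its inputs plus the delta gate.
    """
    for name, p in (("h1_prob", h1_prob), ("h2_prob", h2_prob)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must lie in [0,1]")
    if state.delta_status is not DeltaStatus.VALID:
        return {"action": "continue: conclusions carry a certainty ratio "
                          "while delta is only processed",
                "next_interim": "N3",
                "certainty_ratio": {"H1": h1_prob, "H2": h2_prob}}
    # valid delta from here on
    if 1.0 - h2_prob >= credible:
        return {"action": "stop: tP not different from PEI",
                "next_interim": None}
    if h2_prob >= credible:
        if dose_prob is None:
            raise ValueError("dose decision requested without a dose probability")
        if dose_prob >= credible:
            return {"action": "define min/max effective dose; "
                              "adapt to multisession confirmatory study",
                    "next_interim": None}
        if 1.0 - dose_prob >= credible:
            return {"action": "no dose-response relationship",
                    "next_interim": "N4"}
        return {"action": "continue: dose partially supported",
                "next_interim": "N6"}
    if h1_prob >= credible:
        return {"action": "adapt: eliminate PEI session (SP similar to PEI)",
                "next_interim": "N4"}
    if dose_prob is not None and not (dose_prob >= credible
                                      or 1.0 - dose_prob >= credible):
        return {"action": "continue: dose partially supported",
                "next_interim": "N5"}
    return {"action": "continue: H1/H2 partially supported",
            "next_interim": "N4"}
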