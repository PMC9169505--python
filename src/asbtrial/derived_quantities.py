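"""Functionals of the fitted dose-response curve and the dose mapping.

From the ONLINE logistic segment G_O(j) = f + (c-f)/(1+exp(-d(j-e))) the
clinically interpretable quantities are:

* ``Gain = c - f`` — the potential response gain during stimulation;
* ``DMin``/``DMax`` — the time points at which the mean response first
  exceeds the floor by the minimum clinical efficacy delta, and last sits
  delta below the ceiling:  DMin = e - (1/d) ln((c-f-delta)/delta),
  DMax = e + (1/d) ln((c-f-delta)/delta);
* ``CO = g - a`` — the within-trial carry-over.

The minimum clinical efficacy delta is half the observed PEI (active
control) effect.  Doses are charge-like quantities: stimulation intensity
(mA) times elapsed stimulation minutes at a TLQ probe, with online probes
spaced 2 minutes apart starting at T6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_model import Dataset, PosteriorDraws, Treatment
from .model_core import CurveParams, PARAM_NAMES
from .preprocess import DEFAULT_SCHEME, SegmentScheme, transform_dataset
from . import model_core


class UndefinedDoseError(ValueError):
    """Raised when (c, f, d, delta) leave DMin/DMax undefined."""


@dataclass
class DoseValue:
    intensity_mA: float
    time_min: float

    def __post_init__(self) -> None:
        if self.intensity_mA < 0 or self.time_min < 0:
            raise ValueError("intensity and time must be nonnegative")

    @property
    def dose(self) -> float:
        """mA-minutes."""
        return self.intensity_mA * self.time_min


@dataclass
class MinimumClinicalEfficacy:
    delta: float
    provenance: str  # "descriptive" or "posterior"
    ci_lower: float | None = None
    ci_upper: float | None = None

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be > 0")


def dmin_dmax(c: float, f: float, d: float, e: float,
              delta: float) -> tuple[float, float]:
    """Times where the ONLINE logistic reaches f+delta and c-delta.

    Requires d != 0 and 0 < delta < (c - f)/2, otherwise the crossing
    times do not exist and an :class:`UndefinedDoseError` is raised naming
    the failed inequality.
    """
    if d == 0:
        raise UndefinedDoseError("growth intensity d must be nonzero")
    if delta <= 0:
        raise UndefinedDoseError("delta must be > 0")
    if c - f <= 2 * delta:
        raise UndefinedDoseError(
            f"gain c-f={c - f:.4g} must exceed 2*delta={2 * delta:.4g}")
    spread = math.log((c - f - delta) / delta)
    return e - spread / d, e + spread / d


def gain_and_carryover(params: CurveParams) -> tuple[float, float]:
    """(Gain, CO) = (c - f, g - a)."""
    return params.c - params.f, params.g - params.a


def minimum_clinical_efficacy_descriptive(
    dataset: Dataset, scheme: SegmentScheme = DEFAULT_SCHEME,
) -> MinimumClinicalEfficacy:
    """Delta as half the observed PEI effect on the transformed scale.

    The PEI effect is the mean transformed response over the ONLINE
    segment minus the mean over PRE, pooled across PEI sessions.
    """
    pei = [t for t in transform_dataset(dataset, scheme)
           if t.treatment is Treatment.PEI]
    if not pei:
        raise ValueError("descriptive delta requires at least one PEI series")
    online_idx = [j - 1 for j in scheme.online]
    pre_idx = [j - 1 for j in scheme.pre]
    effect = float(np.mean([t.y[online_idx].mean() - t.y[pre_idx].mean()
                            for t in pei]))
    if effect <= 0:
        raise ValueError(
            f"PEI effect {effect:.4g} is not positive; delta undefined")
    return MinimumClinicalEfficacy(0.5 * effect, "descriptive")


def minimum_clinical_efficacy_posterior(
    draws: PosteriorDraws, start: float = 5.0, level: float = 0.95,
) -> tuple[MinimumClinicalEfficacy, np.ndarray]:
    """Delta distribution = 0.5 * Gain at PEI covariates, per draw."""
    gain = (_curve_quantity_draws(draws, "c", Treatment.PEI, start)
            - _curve_quantity_draws(draws, "f", Treatment.PEI, start))
    delta_draws = 0.5 * gain
    mean = float(delta_draws.mean())
    if mean <= 0:
        raise ValueError("posterior mean PEI gain is not positive; delta undefined")
    lo, hi = np.quantile(delta_draws, [(1 - level) / 2, 1 - (1 - level) / 2])
    return (MinimumClinicalEfficacy(mean, "posterior", float(lo), float(hi)),
            delta_draws)


def control_chart(values) -> dict:
    """Shewhart individuals chart with moving-range natural limits.

    Center = mean; limits = mean +/- 2.66 * mean moving range (the
    individuals-chart constant 3/d2 with d2 for ranges of 2).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("control chart requires at least 2 values")
    center = float(x.mean())
    mr = float(np.mean(np.abs(np.diff(x))))
    lower, upper = center - 2.66 * mr, center + 2.66 * mr
    flagged = [int(i) for i in np.nonzero((x < lower) | (x > upper))[0]]
    return {"center": center, "lower": lower, "upper": upper,
            "mean_moving_range": mr, "out_of_limits": flagged}


# ---------------------------------------------------------------------------
# posterior treatment contrasts


def _curve_quantity_draws(draws: PosteriorDraws, param: str,
                          treatment: Treatment, start: float) -> np.ndarray:
    x = model_core.design_row(treatment, start)
    total = np.zeros(draws.n_chains * draws.n_iterations)
    for k, cov in enumerate(model_core.COVARIATE_NAMES):
        total += x[k] * draws.flat(f"beta_{param}_{cov}")
    return total


def curve_draws(draws: PosteriorDraws, treatment: Treatment,
                start: float = 5.0) -> dict[str, np.ndarray]:
    """Per-draw curve quantities a..h at the population level."""
    return {p: _curve_quantity_draws(draws, p, treatment, start)
            for p in PARAM_NAMES}


def mu_draws_at(draws: PosteriorDraws, treatment: Treatment, timepoints,
                start: float = 5.0, transient_mode: str = "midpoint") -> np.ndarray:
    """Posterior draws of the population mean response averaged over
    the requested time points."""
    cp = curve_draws(draws, treatment, start)
    n = next(iter(cp.values())).size
    params = np.column_stack([cp[p] for p in PARAM_NAMES])
    mus = model_core.mu_matrix(params, np.zeros(n), np.zeros(n), transient_mode)
    idx = [int(j) - 1 for j in np.atleast_1d(timepoints)]
    return mus[:, idx].mean(axis=1)


def treatment_contrast(draws: PosteriorDraws, pair: tuple, timepoints,
                       delta: float, start: float = 5.0,
                       level: float = 0.95,
                       transient_mode: str = "midpoint") -> dict:
    """Posterior contrast of mean responses between two treatments.

    Returns the posterior mean difference, an equal-tailed credible
    interval, the superiority probability P(diff > delta) and the
    ROPE-style equivalence probability P(|diff| < delta).
    """
    t1, t2 = (Treatment.parse(t) for t in pair)
    diff = (mu_draws_at(draws, t1, timepoints, start, transient_mode)
            - mu_draws_at(draws, t2, timepoints, start, transient_mode))
    lo, hi = np.quantile(diff, [(1 - level) / 2, 1 - (1 - level) / 2])
    return {
        "pair": (t1.value, t2.value),
        "mean_difference": float(diff.mean()),
        "ci_lower": float(lo),
        "ci_upper": float(hi),
        "p_superior": float(np.mean(diff > delta)),
        "p_equivalent": float(np.mean(np.abs(diff) < delta)),
    }


# ---------------------------------------------------------------------------
# dose mapping


@dataclass(frozen=True)
class StimulationTimeline:
    """Maps model time points to minutes since stimulation onset.

    Default: stimulation starts at the T6 probe and online probes are
    2 minutes apart, so minutes = spacing * (j - onset).
    """

    onset_timepoint: int = 6
    probe_spacing_min: float = 2.0

    def minutes_at(self, timepoint: float) -> float:
        if timepoint < self.onset_timepoint:
            raise ValueError(
                f"timepoint {timepoint} precedes stimulation onset "
                f"T{self.onset_timepoint}")
        return self.probe_spacing_min * (timepoint - self.onset_timepoint)


DEFAULT_TIMELINE = StimulationTimeline()


def dose_at(timepoint: float, intensity_mA: float = 2.0,
            timeline: StimulationTimeline = DEFAULT_TIMELINE) -> DoseValue:
    """Dose (mA-min) delivered by a TLQ probe time: intensity x minutes."""
    return DoseValue(intensity_mA, timeline.minutes_at(timepoint))


def effective_doses(c: float, f: float, d: float, e: float, delta: float,
                    intensity_mA: float = 2.0,
                    timeline: StimulationTimeline = DEFAULT_TIMELINE,
                    ) -> tuple[DoseValue, DoseValue]:
    """Minimum and maximum effective doses from the logistic crossing times."""
    dmin, dmax = dmin_dmax(c, f, d, e, delta)
    return dose_at(dmin, intensity_mA, timeline), dose_at(dmax, intensity_mA, timeline)
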