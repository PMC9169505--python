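"""Hierarchical piecewise nonlinear model for the transformed TLQ response.

For subject i at time point j the transformed response is

    Y_ij | mu_ij, sigma2 ~ N(mu_ij, sigma2)

with a segment-wise mean:

    PRE   (j = 1..5):    G_P = a_i + b_i (j - 5)
    TRANS (j = 6):       G_T = (a_i + f_i)/2 + gammaT_i
    ONLINE(j = 7..16):   G_O = f_i + (c_i - f_i) / (1 + exp(-d_i (j - e_i)))
    POST  (j = 17..21):  G_S = c_i + (g_i - c_i) (1 - exp(-h_i (j - 16)))

plus a per-session occasion effect gamma_O.  The transient value at T6 is
read as the midpoint between the PRE endpoint ``a`` and the ONLINE floor
``f`` plus its own subject-level random deviation; an alternative reading
``f + a/2`` is available via ``transient_mode="half_a"``.

Each curve quantity o in {a..h} is a linear function of treatment and
baseline covariates:

    o_i = beta0_o + beta1_o 1[SP] + beta2_o 1[tP] + beta3_o Start_i + gamma_o_i

with PEI the reference treatment and Start the raw response at T1.
Subject-level random effects are independent normals with a diagonal
covariance; the default active set is {c, e, f, T} (the quantities whose
between-subject variability dominates in this design), the full nine-effect
set being available through :class:`RandomEffectsSpec`.

Priors are independent normals on the coefficients and Gamma priors on the
precisions (1/variance); the defaults mirror the informative prior choices
used for this trial design (e.g. the PRE-end level centred at 5 on the
shifted scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_model import Treatment, N_TIMEPOINTS
from .preprocess import TransformedSeries

PARAM_NAMES = ("a", "b", "c", "d", "e", "f", "g", "h")
COVARIATE_NAMES = ("Intercept", "SP", "tP", "Start")
RANDOM_EFFECT_NAMES = PARAM_NAMES + ("T",)

#: Time-point layout shared with :mod:`asbtrial.preprocess`.
PRE_J = np.arange(1, 6)
TRANSIENT_J = 6
ONLINE_J = np.arange(7, 17)
POST_J = np.arange(17, 22)


@dataclass
class CurveParams:
    """The eight interpretable quantities governing one trajectory's mean."""

    a: float  # level at the end of PRE
    b: float  # PRE slope
    c: float  # ONLINE maximum
    d: float  # ONLINE growth intensity
    e: float  # ONLINE inflection time
    f: float  # ONLINE minimum
    g: float  # POST minimum
    h: float  # POST decay intensity
    gammaT: float = 0.0  # transient random deviation

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])


@dataclass
class FixedEffects:
    """8x4 coefficient matrix: rows a..h, columns (Intercept, SP, tP, Start)."""

    beta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (8, 4):
            raise ValueError(f"beta must be 8x4, got {self.beta.shape}")

    def row(self, name: str) -> np.ndarray:
        return self.beta[PARAM_NAMES.index(name)]


@dataclass
class RandomEffectsSpec:
    """Active subject-level effects with variances, plus occasion and noise."""

    active: tuple[str, ...] = ("c", "e", "f", "T")
    lambda2: dict = field(default_factory=lambda: {
        "c": 0.5, "e": 0.5, "f": 0.5, "T": 0.5})
    lambda2_occasion: float = 0.25
    sigma2: float = 0.2

    def __post_init__(self) -> None:
        unknown = set(self.active) - set(RANDOM_EFFECT_NAMES)
        if unknown:
            raise ValueError(f"unknown random effects {sorted(unknown)}")
        for k in self.active:
            if self.lambda2.get(k, 0.0) < 0:
                raise ValueError(f"variance for effect {k} must be >= 0")
        if self.lambda2_occasion < 0 or self.sigma2 <= 0:
            raise ValueError("occasion variance must be >= 0 and sigma2 > 0")


def default_priors() -> "PriorSpec":
    """Informative defaults: normals on coefficients, Gamma(0.001, 0.001)
    on every precision.  Second normal argument is a *variance*."""
    intercepts = {"a": (5.0, 0.1), "b": (0.0, 0.1), "c": (4.0, 1.0),
                  "d": (2.0, 0.25), "e": (11.0, 1.0), "f": (4.5, 2.0),
                  "g": (5.0, 0.1), "h": (0.0, 0.1)}
    coef = {}
    for p in PARAM_NAMES:
        coef[f"beta_{p}_Intercept"] = intercepts[p]
        coef[f"beta_{p}_SP"] = (0.0, 0.25)
        coef[f"beta_{p}_tP"] = (0.0, 0.25)
        coef[f"beta_{p}_Start"] = (0.0, 0.001)
    return PriorSpec(coefficients=coef, precision_shape=0.001, precision_rate=0.001)


@dataclass
class PriorSpec:
    """Normal(location, variance) priors per coefficient; Gamma(shape, rate)
    priors on precisions 1/sigma2 and 1/lambda2."""

    coefficients: dict
    precision_shape: float = 0.001
    precision_rate: float = 0.001

    def __post_init__(self) -> None:
        for name, (loc, var) in self.coefficients.items():
            if var <= 0:
                raise ValueError(f"prior variance for {name} must be > 0")
        if self.precision_shape <= 0 or self.precision_rate <= 0:
            raise ValueError("Gamma hyperparameters must be > 0")

    def coefficient_array(self) -> tuple[np.ndarray, np.ndarray]:
        """(locations, variances) as 8x4 arrays aligned with FixedEffects."""
        loc = np.empty((8, 4))
        var = np.empty((8, 4))
        for i, p in enumerate(PARAM_NAMES):
            for k, c in enumerate(COVARIATE_NAMES):
                loc[i, k], var[i, k] = self.coefficients[f"beta_{p}_{c}"]
        return loc, var


# ---------------------------------------------------------------------------
# Mean curve


def transient_value(a: float, f: float, gammaT: float = 0.0,
                    mode: str = "midpoint") -> float:
    """Mean at the transient probe T6 bridging PRE and ONLINE."""
    if mode == "midpoint":
        return (a + f) / 2.0 + gammaT
    if mode == "half_a":
        return f + a / 2.0 + gammaT
    raise ValueError(f"unknown transient mode {mode!r}")


def mu(j: int, p: CurveParams, occasion_effect: float = 0.0,
       transient_mode: str = "midpoint") -> float:
    """Mean response at a single time point."""
    if not 1 <= j <= N_TIMEPOINTS:
        raise ValueError(f"timepoint {j} outside 1..{N_TIMEPOINTS}")
    if j <= 5:
        base = p.a + p.b * (j - 5)
    elif j == TRANSIENT_J:
        base = transient_value(p.a, p.f, p.gammaT, transient_mode)
    elif j <= 16:
        base = p.f + (p.c - p.f) / (1.0 + math.exp(-p.d * (j - p.e)))
    else:
        base = p.c + (p.g - p.c) * (1.0 - math.exp(-p.h * (j - 16)))
    return base + occasion_effect


def mu_matrix(params: np.ndarray, gammaT: np.ndarray,
              occasion: np.ndarray, transient_mode: str = "midpoint") -> np.ndarray:
    """Vectorised mean curves.

    ``params`` is (n_series, 8) in a..h order, ``gammaT`` and ``occasion``
    are length n_series; returns (n_series, 21).
    """
    a, b, c, d, e, f, g, h = (params[:, k][:, None] for k in range(8))
    out = np.empty((params.shape[0], N_TIMEPOINTS))
    out[:, :5] = a + b * (PRE_J[None, :] - 5)
    if transient_mode == "midpoint":
        out[:, 5] = ((a + f) / 2.0)[:, 0] + gammaT
    elif transient_mode == "half_a":
        out[:, 5] = (f + a / 2.0)[:, 0] + gammaT
    else:
        raise ValueError(f"unknown transient mode {transient_mode!r}")
    out[:, 6:16] = f + (c - f) / (1.0 + np.exp(-d * (ONLINE_J[None, :] - e)))
    out[:, 16:] = c + (g - c) * (1.0 - np.exp(-h * (POST_J[None, :] - 16)))
    return out + np.asarray(occasion)[:, None]


def design_row(treatment: Treatment, start: float) -> np.ndarray:
    """Covariate vector (1, 1[SP], 1[tP], Start); PEI is the reference."""
    return np.array([1.0,
                     1.0 if treatment is Treatment.SP else 0.0,
                     1.0 if treatment is Treatment.TP else 0.0,
                     float(start)])


def linear_predictor(beta_row: np.ndarray, treatment: Treatment,
                     start: float, subject_effect: float = 0.0) -> float:
    """One curve quantity: x' beta + subject random effect."""
    return float(design_row(treatment, start) @ np.asarray(beta_row)) + subject_effect


def curve_params_for(fixed: FixedEffects, treatment: Treatment, start: float,
                     subject_effects: dict | None = None) -> CurveParams:
    eff = subject_effects or {}
    values = {p: linear_predictor(fixed.row(p), treatment, start, eff.get(p, 0.0))
              for p in PARAM_NAMES}
    return CurveParams(**values, gammaT=eff.get("T", 0.0))


# ---------------------------------------------------------------------------
# Joint density


def log_likelihood(series: list[TransformedSeries], mu_values: np.ndarray,
                   sigma2: float) -> float:
    """Gaussian log-likelihood of the transformed responses.

    ``mu_values`` is (n_series, 21) aligned with ``series``.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    y = np.stack([s.y for s in series])
    resid = y - mu_values
    n = resid.size
    return float(-0.5 * n * math.log(2.0 * math.pi * sigma2)
                 - 0.5 * np.sum(resid ** 2) / sigma2)


def _normal_logpdf(x: np.ndarray, loc: np.ndarray, var: np.ndarray) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - loc) ** 2 / var)


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    if x <= 0:
        return -np.inf
    return (shape * math.log(rate) - math.lgamma(shape)
            + (shape - 1.0) * math.log(x) - rate * x)


def log_prior(fixed: FixedEffects, variances: dict, priors: PriorSpec,
              random_effects: dict | None = None,
              occasion_effects: np.ndarray | None = None,
              lambda2_occasion: float | None = None) -> float:
    """Log prior density of coefficients, precisions and random effects.

    ``variances`` maps names like ``sigma2`` / ``lambda2_c`` to values; the
    Gamma priors act on the corresponding precisions.  When subject or
    occasion random effects are supplied, their N(0, variance) terms are
    included.
    """
    loc, var = priors.coefficient_array()
    total = float(np.sum(_normal_logpdf(fixed.beta, loc, var)))
    for name, v in variances.items():
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
        # Gamma prior on the precision; includes the change-of-variables
        # Jacobian so this is the density of the *variance*.
        prec = 1.0 / v
        total += _gamma_logpdf(prec, priors.precision_shape, priors.precision_rate)
        total += -2.0 * math.log(v)
    if random_effects:
        for name, values in random_effects.items():
            v = variances[f"lambda2_{name}"]
            total += float(np.sum(_normal_logpdf(np.asarray(values), 0.0, v)))
    if occasion_effects is not None:
        if lambda2_occasion is None:
            raise ValueError("lambda2_occasion required with occasion_effects")
        total += float(np.sum(_normal_logpdf(np.asarray(occasion_effects), 0.0,
                                             lambda2_occasion)))
    return total


def log_posterior(series: list[TransformedSeries], mu_values: np.ndarray,
                  sigma2: float, fixed: FixedEffects, variances: dict,
                  priors: PriorSpec, **prior_kwargs) -> float:
    """log_likelihood + log_prior, exactly."""
    return (log_likelihood(series, mu_values, sigma2)
            + log_prior(fixed, variances, priors, **prior_kwargs))
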