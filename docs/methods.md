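# Methods

## Response transform

Raw TLQ trajectories (21 probes, integer 1–10) are converted to the
modelled response in three steps.  Detrending subtracts a fixed reference
probe per segment: T1 for PRE (T1–T5), T5 — the last pre-stimulation
probe — for the transient probe T6 and the ONLINE window (T6–T16), and
T16 for POST (T17–T21).  Each point therefore measures cumulative change
within its segment, which suppresses slow drift across the session.  The
detrended series is negated so that larger values mean larger loudness
*reduction*, and shifted by a constant (default 5, matching the prior
location of the PRE-end level so the working scale is positive).  The
transform is exactly invertible given the raw value at T1; the simulator
uses that inverse.

Two conventions are worth flagging.  The PRE reference is T1, its first
probe (the alternative — a fitted within-segment stability point — is
not identifiable from 5 points and is not used).  T6 is treated as a
transient probe with the ONLINE reference, mirroring the model's
segmentation below.

## Model

For subject i, time point j:

Y_ij | μ_ij, σ² ~ N(μ_ij, σ²), with μ_ij piecewise: linear a_i + b_i(j−5)
over PRE; the transient value at j=6; a four-parameter logistic
f_i + (c_i−f_i)/(1+exp(−d_i(j−e_i))) over ONLINE; and exponential decay
c_i + (g_i−c_i)(1−exp(−h_i(j−16))) over POST.  A per-session occasion
effect γ_O ~ N(0, λ_O²) is added at every j.  The model is deliberately
discontinuous at the segment boundaries; no continuity constraint is
imposed.

The transient mean is the midpoint (a_i+f_i)/2 plus its own subject-level
deviation γT.  The alternative reading f_i + a_i/2 is available via
`transient_mode="half_a"`; the midpoint is the default because it bridges
the PRE endpoint and the ONLINE floor on the same scale regardless of
their values.

Each curve quantity ∘ ∈ {a..h} is x_i'β∘ + γ∘_i with covariates
(1, 1[SP], 1[tP], Start): PEI is the reference arm and Start is the raw
response at T1, entered uncentred on its 1–10 scale (its prior is tight,
N(0, 0.001), consistent with a small uncentred effect).  Subject random
effects are independent normals with a diagonal covariance; the default
active set is {c, e, f, T} — the quantities whose between-subject
variability dominates in this design — and the full nine-effect set is
available through `RandomEffectsSpec`.  Random effects are indexed by
subject and shared across that subject's three sessions; occasion effects
are drawn once per subject-session.

Priors (all configurable; `N(m, v)` has variance v): intercepts
a ~ N(5, 0.1), b ~ N(0, 0.1), c ~ N(4, 1), d ~ N(2, 0.25), e ~ N(11, 1),
f ~ N(4.5, 2), g ~ N(5, 0.1), h ~ N(0, 0.1); treatment effects
N(0, 0.25); Start effects N(0, 0.001); every precision (1/σ², 1/λ²)
Gamma(0.001, 0.001).  The occasion variance gets the same Gamma prior as
the subject-effect variances.

## Sampler

No general-purpose probabilistic-programming backend is used; the sampler
is an adaptive Metropolis-within-Gibbs scheme written for this model:

- each 4-vector β∘ is one random-walk block; during burn-in the proposal
  covariance adapts to the running empirical covariance of the block
  (scaled 2.38²/4, Haario-style) with an acceptance-tuned global scale,
  frozen at the end of burn-in so the retained chain is valid;
- subject and occasion random effects use element-wise proposals with
  per-subject / per-session acceptance, valid because the likelihood and
  priors factorise across subjects and sessions;
- a translation move proposes β∘₀ → β∘₀+δ, γ∘ → γ∘−δ jointly for each
  active effect.  It leaves the likelihood untouched and is accepted on
  the prior ratio alone; without it the intercepts and the mean of their
  random effects drift against each other and mixing is poor
  (Gelman–Rubin ≈ 2–3 at 2,000 iterations; ≈ 1.0–1.1 with the move);
- all variances have conjugate inverse-Gamma full conditionals and are
  updated by Gibbs steps.

Initialisation is at the prior locations with seeded jitter (bounded
retries if the initial log-posterior is not finite).  Chains use
independent streams spawned from the seed; runs are bit-reproducible.

## Diagnostics

Gelman–Rubin is the Brooks–Gelman factor sqrt(((n−1)/n·W + B/n)/W).
Geweke compares the first 10% and last 50% window means, normalised by
each window's spectral density at zero.  The spectral density is
estimated by an AR fit (Yule–Walker, AIC order selection),
s0 = σ²/(1−Σφ)².  Heidelberger–Welch tests the Cramér–von Mises
statistic of the cumulative-sum bridge against its asymptotic law, with
s0 estimated from the *second half* of the retained chain — estimating it
from the whole chain lets an early mean shift inflate s0 and mask itself
(the behaviour of some reference implementations, which then rely on the
halfwidth test to flag the problem).  On failure the initial 10% is
discarded and the test repeated while at least 60% of the chain remains;
the halfwidth test then compares the 95% halfwidth of the retained mean
to 10% of its magnitude.  The asymptotic Cramér–von Mises tail is
evaluated by the classical Bessel-K series, truncated at 12 terms and
clamped to 0 beyond statistic 1.0 where the survival probability is below
~5·10⁻⁴.

Summaries report posterior mean, SD, equal-tailed interval, naive SE
(sd/√N) and time-series SE (√(s0/N), s0 averaged over chains so the
result is invariant to chain order); Geweke and Heidelberger–Welch are
computed per chain and the smallest p-value reported.

## Derived quantities and the adaptive engine

δ (minimum clinical efficacy) is half the PEI effect.  Descriptively that
is half the difference between the mean transformed ONLINE and PRE
responses under PEI; as a posterior it is 0.5·Gain at the PEI covariates
per draw.  Because the logistic averages roughly midway between floor and
ceiling over the ONLINE window, the descriptive value is typically about
half the gain-based posterior value; both are reported where relevant.
DMin/DMax require c − f > 2δ and d ≠ 0 and satisfy G_O(DMin) = f + δ,
G_O(DMax) = c − δ exactly.  Control charts are Shewhart individuals
charts with natural limits mean ± 2.66 × mean moving range.  Treatment
contrasts are per-draw differences of population mean curves at requested
time points, giving P(diff > δ) and the ROPE-style P(|diff| < δ).

Uncertainty reduction between interims: posterior expected values are
compared with a normal-approximation Bayes factor (point null against a
diffuse alternative whose scale is 10× the pooled posterior spread —
with a narrower alternative even identical posteriors cannot clear the
conventional threshold BF01 > 3); given equivalence, UR = (1 −
L_curr/L_prev) × 100% from the 95% equal-tailed interval lengths, or from
posterior coefficients of variation in `mode="cv"`.

The δ state machine declares a new posterior "within the credibility
margin" when its 95% interval length is at most half the posterior mean
(both fractions configurable; no numeric rule is inherited, so this is a
design choice).  The decision engine is a pure function of the δ status
and the H1/H2/Dose posterior probabilities at a credibility threshold
(default 0.95): futility stops the study, credible H1 eliminates the PEI
session, credible H2+Dose fixes the dose window and moves to the
multisession study, and partial evidence routes to the N3/N4/N5/N6
interims (N6 is N5 recomputed conditional on credible H2).

## Sample-size calculators

The three interim calculators expose named default formulas behind a
strategy interface (the trial report tabulates results whose defining
expressions were not published in machine-readable form; the defaults are
standard z-based forms): N3 detects a CV change,
(z_{1−α/2}+z_{1−β})²(cv₁²+cv₂²)/(cv₂−cv₁)²; N4 a repeated-measures mean
difference, groups·z²·σ²(1+(m−1)ρ)/(mδ²); N5 a nonzero linear contrast,
z²·σ²·Σc²/(Σcμ)².  On the pilot's inputs these give 12, 19 and 10.
`posterior_sample_size` evaluates any calculator per posterior draw,
excludes (and counts) draws violating its preconditions, and returns the
n-distribution with a nondecreasing sequential plan at the 25/50/75/90%
quantiles.  The ICC helper implements ρ = σ₀²/(σ₀²+σ²).

## Simulator

`simulate_dataset` draws Williams sequences, random effects and noise,
evaluates the mean curve, and inverts the response transform segment by
segment to raw trajectories, rounding half away from zero and clamping to
1–10 (real TLQ is an integer key press); a warning is recorded if more
than 20% of values clamp.  Generating defaults emulate the pilot
conditions: flat PRE at the shifted reference (a=5, b=0), an online rise
from 5 toward 5.8 under the active control (gain 0.8, hence δ ≈ 0.4 on
the gain scale), d=2, e=11, modest carry-over (g=5.3, h=0.3), small
treatment effects (+0.2/+0.5 on c for SP/tP, −0.5 on e for tP), no
baseline effect, subject-effect variances 0.1 on {c, e, f} (0.05 on T),
occasion variance 0.05, σ²=0.2, baselines uniform on {4..8}.

What the generator does *not* emulate: ordinal measurement beyond
rounding (no response styles, no floor/ceiling psychology), serial
correlation beyond the occasion effect, missing data, or learning across
sessions.  Passing tests therefore validate the estimation machinery
under the model's own assumptions plus integer coarsening — not
robustness to real-data artefacts.

Rounding interacts with the transform in one important way: coarsening
the segment *reference* probes (T5, T16) shifts a whole segment of the
transformed response by up to ±0.5 coherently, a segment-level noise
component the model does not carry.  In recovery experiments this leaves
population intercepts essentially unbiased but makes credible intervals
for session-level contrasts (treatment effects on c, h) somewhat
overconfident.  The parameter-recovery acceptance experiment therefore
simulates the continuous response model (`round_to_likert=False`): it is
a calibration check of the fitting machinery against its own generative
model.

## Problem sizes and budgets

The recovery experiment uses 20 replicates of 20 subjects (60 series,
1,260 observations each), 2 chains × 3,000 iterations (1,000 burn-in,
2,000 retained), about 2 minutes total; the acceptance script repeats it
at 10 replicates and adds a six-subject pilot fit at the same chain
settings.  These sizes give Monte-Carlo error small enough for the
properties asserted while keeping a full test run in a few minutes.  Note
that "90% intervals cover in ≥80% of 20 replicates for every one of 32
coefficients" is a strict bar: under perfect calibration per-parameter
coverage is Binomial(20, 0.9), so the familywise chance of at least one
count below 16/20 is roughly one in three; the informative priors (truth
within about one prior SD for the tightly-prior'd POST parameters) keep
realised coverage above nominal.

## Known limitations

- The sampler is a random-walk scheme: adequate at these problem sizes,
  but gradient-based samplers would scale better to many subjects.
- λ_O² and the weakly identified d, h rely on their priors at pilot
  scale.
- The descriptive and posterior δ operationalisations differ by design
  (window average vs gain); users comparing them should expect a factor
  of about two.
- The protocol compiler reconstructs the PRE/POST interleaving of
  resting-state and Stroop blocks from the published ordering rule; the
  exact event list was never printed, and the layout is overridable.
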