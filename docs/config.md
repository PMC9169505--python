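# Config file schema

A single YAML document can drive the CLI subcommands.  All keys are
optional; omitted keys fall back to the documented defaults.

```yaml
model:
  transient_mode: midpoint        # or half_a
  shift_constant: 5.0
  priors:                         # name: [location, variance]
    beta_c_Intercept: [4.0, 1.0]
    beta_c_tP: [0.0, 0.25]
  random_effects: [c, e, f, T]    # active subject-level effects

truth:                            # simulator generating values
  start_values: [4, 5, 6, 7, 8]
  round_to_likert: true

samplesize:                       # inputs for the `samplesize` subcommand
  cv1: 0.0598                     # cv_difference
  cv2: 0.367
  # sigma2_total, icc, m, delta  -> repeated_measures
  # means, contrasts, sigma2     -> dose_contrast
```

Stochastic subcommands (`simulate`, `fit`, `protocol`) require an
explicit `--seed`; sampler controls (chains, iterations, burn-in,
thinning) are CLI flags on `fit`.
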