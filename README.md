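# contactfatigue

Bayesian estimation of social contact intensities from longitudinal
survey panels, with detection and correction of **reporting fatigue** —
the progressive under-reporting of contacts by panel members as their
number of repeat participations grows.

Social contact surveys (CoMix-style panels such as the German COVIMOD
study) are a key input to epidemic models: they measure the expected
number of close contacts per person per day. In longitudinal panels the
same participants answer repeatedly, and their reported contact counts
decline with the number of prior participations even when behaviour does
not change. Left uncorrected, this bias propagates into any
contact-based estimate of transmission. This package implements, as a
tested reusable pipeline, a fatigue-aware modelling workflow exercised
end-to-end on synthetic cohorts with known ground truth:

1. **Data model** — long-format participant/contact tables, missing
   demographic filtering, child-age imputation, truncation of contact
   totals at 30, repeat-count derivation, and one-hot design blocks
   (21 always-in + 16 tested + 33 fatigue columns).
2. **Synthetic cohorts** — multi-wave panels with Bernoulli retention and
   quota recruitment, covariate-driven log-linear intensities, a smooth
   calendar trend, Hill-shaped multiplicative fatigue and
   negative-binomial noise.
3. **Variable selection** — Poisson regression with a regularized
   horseshoe (RHS) prior on tested features; a feature is relevant when
   its posterior median changes baseline intensity by more than ±5%
   (outside (log 0.95, log 1.05) ≈ (−0.0513, 0.0488)). Fatigue
   determinants use a negative half-RHS prior with the (1 − 2/π)⁻¹
   variance-matching adjustment; selections are unioned across waves.
4. **Fatigue dynamics** — a longitudinal negative-binomial model
   log λ = β₀ + xᵀβ + τ(t) + ρ(r) with a Matérn-3/2 Gaussian-process
   calendar trend τ and four interchangeable fatigue forms ρ(r):
   independent per-repeat effects, one shared effect, a GP over repeat
   counts, and the three-parameter **Hill dose-response**

       ρ(r) = −γ · e^ζ r^η / (1 + e^ζ r^η),    ρ(0) = 0,  ρ(∞) = −γ,

   whose asymptote implies a maximum reporting reduction of
   100·(e^(−γ) − 1) percent.
5. **De-biasing GAM** — a negative-binomial generalized additive model
   with a Hilbert-space approximate GP (HSGP) age smooth and independent
   Hill adjustments per selected fatigue feature; includes the
   incremental-inclusion accuracy experiment (MAPE and baseline coverage
   versus a first-timer-only fit) and sequential wave-to-wave fitting
   with priors centred on the previous wave's posterior means.
6. **Post-stratification** — population and subgroup contact-intensity
   estimates reweighted to census margins (age group × sex × household
   size), fatigue-free by construction (Hill term evaluated at r = 0),
   plus a simple participant-level bootstrap comparator.

All posteriors are sampled with affine-invariant ensemble MCMC
(`emcee`) started from a MAP point, with rank-normalized R-hat and
acceptance-fraction diagnostics surfaced on every fit.

## Worked example

```python
import numpy as np
import contactfatigue as cf
from contactfatigue.data_model import build_design
from contactfatigue.fatigue import FatigueModelSpec
from contactfatigue.synthetic import GeneratorConfig, generate_cohort

cfg = GeneratorConfig(n_per_wave=640, n_waves=10, rng_seed=7)  # truth: Hill(0.88, -1.55, 0.94)
panel = build_design(generate_cohort(cfg))
fit = cf.fit_longitudinal_model(panel, FatigueModelSpec(variant="hill"),
                                seed=5, n_warmup=2500, n_steps=1500)
print(f"gamma {fit.median('gamma'):.2f}, zeta {fit.median('zeta'):.2f}, "
      f"eta {fit.median('eta'):.2f}")
print(cf.reduction_curve(fit).round(1).head(4))
```

Output (a few minutes on one CPU):

```
gamma 0.75, zeta -1.68, eta 1.19
   r  median  lower95  upper95
0  0     0.0      0.0      0.0
1  1   -11.4    -17.3     -6.4
2  2   -20.5    -25.9    -15.1
3  3   -26.9    -31.7    -21.8
```

Read: the fitted Hill curve estimates that a participant's third repeat
participation already suppresses their reported contacts by about 27%
(posterior median), and the generating parameters (γ = 0.88, ζ = −1.55,
η = 0.94) are recovered within their published uncertainty.

The numbered scripts under `analysis/` run the full pipeline —
simulation, two-wave feature selection, fatigue-dynamics comparison,
the incremental de-biasing experiment and post-stratified population
estimates — writing tidy CSV tables under `results/`.

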