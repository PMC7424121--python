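# morphcp

Analysis pipeline for **categorical perception of facial identity** measured
with morph continua: trial-level two-alternative forced-choice (2AFC) data —
"which of these two identities does this blended face resemble?" — are turned
into response curves, boundary-shift effect sizes, the asymmetry-bias
statistic, and mixed-model inference. It is written for visual-psychophysics
researchers studying how familiarity (a friend's face, one's own face) moves
the categorical boundary along a morph continuum, and ships a synthetic-data
generator that emulates the two standard designs (blocked
familiar/unfamiliar continua and intermixed stranger/friend/self continua)
for testing and power analysis.

## The statistics at the core

For morph level *m* (percent of "Identity B" in the blend, 10–90% in steps
of 10) the response curve is f(m), the mean percent of Identity-B choices.
The package implements:

* **Symmetrization** for control continua whose B-label is arbitrary:
  f′(x) = (f(x) + 100 − f(100−x))/2, with f′(50) = 50 exactly.
* **Percentile bootstrap CIs**, resampling participants (and re-randomizing
  arbitrary continuum labels per replicate).
* **Effect sizes**: per-level percentage-point differences between a
  familiarity condition and its control, with paired bootstrap CIs.
* **Asymmetry bias** within a condition:
  bias(x) = f(x) − (100 − f(100−x)) for x ≤ 40 and bias(50) = f(50) − 50;
  negative values mean the familiar label is used conservatively.
* **Binomial GLMM** (logit link) for choices with fixed effects
  scaled-morph × condition (zero-sum contrasts) and crossed random
  intercepts for participant and continuum, fitted by a from-scratch
  Laplace approximation (penalized IRLS inner step, derivative-free outer
  optimization over variance components).
* **Linear mixed model** for log RTs (exact marginal ML) on trials passing
  the standard filters (150 ms–5 s window, correct responses, no 50%
  morphs).
* **Type-3 Wald chi-square tests** per model term and **PSE** (point of
  subjective equality) estimates with delta-method standard errors.

See `docs/methods.md` for model details, defaults, and numerical choices.

## Worked example

```python
from morphcp import (SimulationConfig, simulate, response_curve,
                     fit_binomial_glmm, wald_type3, estimate_pse)
from morphcp.fixtures import exp1_familiar_curve, exp1_control_curve
from morphcp.effects_bias import effect_size

# packaged reference curves from the blocked experiment
eff = effect_size(exp1_familiar_curve(), exp1_control_curve(),
                  "reference_minus_condition")
print(eff.effect[50], eff.effect[40])   # 8.7, 3.9

# simulate a blocked-design experiment and analyze it
trials, continua, truth = simulate(SimulationConfig(design="exp1", seed=42))
curve = response_curve(trials, "unfamiliar_familiar", n_boot=2000, seed=0)
print(f"f(50) = {curve.f[50]:.1f} [{curve.ci_low[50]:.1f}, {curve.ci_high[50]:.1f}]")

fit = fit_binomial_glmm(trials)
print(wald_type3(fit).as_frame())
est = estimate_pse(fit, "unfamiliar_familiar", reference="unfamiliar_unfamiliar")
print(f"PSE {est.pse:.1f}, shift {est.shift:.1f} ± {est.shift_se:.1f}")
```

Output:

```
8.700000000000003 3.8999999999999986
f(50) = 38.0 [29.4, 46.7]
       term  chi_square  df  p_value
      morph 2756.694308   1 0.000000
  condition    3.343197   1 0.067483
interaction    0.150281   1 0.698267
PSE 54.4, shift 2.4 ± 1.3
```

Reading it: on the packaged reference curves, the 50% morph is labeled as
the familiar identity 8.7 percentage points less often than in the control
condition. In the simulated experiment the 50% morph between a familiar and
unfamiliar face draws only ~38% "familiar" responses, and the fitted
categorical boundary sits at morph level 54.4 — shifted toward the familiar
endpoint relative to the control continua (this particular seed
under-estimates the generating 5-unit shift; the continuum intercepts of a
six-continuum design add real uncertainty to the contrast).

## Command line

```bash
morphcp simulate --design exp1 --seed 1 --out sim/        # trials + truth
morphcp analyze sim/trials.csv --model choice --out fit/  # one model, JSON
morphcp report sim/trials.csv --experiment exp1 --out report/  # full bundle
morphcp fixtures --out tables/                            # packaged tables
```

`report` writes tidy tables (`curves.csv`, `rt_curves.csv`, `effects.csv`,
`bias.csv`, `pse.csv`), model JSON reports with Wald tables, the filter
report, and a run log; identical configurations reproduce the bundle byte
for byte.

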