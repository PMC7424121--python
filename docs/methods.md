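# Methods

`morphcp` analyzes two-alternative forced-choice (2AFC) identity judgments
on morph continua between two face identities. This note documents the
statistical model behind each stage, the defaults and why they were chosen,
what the synthetic-data generator does and does not emulate, and the
numerical choices that matter for reproducing results.

## Data model and filtering

A trial records which participant saw which morph (the percent of
"Identity B" in the blend, one of 10–90% in steps of 10) from which
continuum, the chosen identity (`A`/`B`), and the reaction time in ms.
Identity B is the *more familiar* endpoint where familiarity differs
(unfamiliar–familiar, stranger–friend, stranger–self, friend–self); in the
two control conditions (unfamiliar–unfamiliar, stranger–stranger,
friend–friend) the designation is arbitrary, which drives the
symmetrization described below.

Reaction-time analyses use only trials that pass three filters, applied in
this order, with every removal attributed to the first rule that fires:

1. RT window 150 ms–5 s. The bounds are treated as *inclusive*: only
   strictly faster/slower trials are discarded. The exclusion is usually
   phrased as "shorter than 150 ms / longer than 5 s", and we take that
   wording literally; at most a handful of trials can sit exactly on a
   bound, so the choice is immaterial in practice but is fixed here for
   reproducibility.
2. Removal of 50% morphs, where no correct answer exists.
3. Removal of incorrect responses, correctness meaning the chosen identity
   contributed the majority of the morph.

The `FilterReport` partitions the input exactly; a property test checks
this on random tables.

## Response curves and symmetrization

The response curve f(m) is the mean percent Identity-B response at each
morph level. Aggregation averages participant-level percentages with equal
weight (with balanced designs this equals the pooled trial proportion; a
`pooled` mode is available). Levels with no trials are reported as missing,
never as zero.

For arbitrary-label control conditions the raw curve depends on which
endpoint was (arbitrarily) called B. Symmetrization removes that
dependence:

    f'(x) = (f(x) + 100 − f(100−x)) / 2,   f'(50) = 50 exactly.

The operation is idempotent and forces point symmetry
f'(x) + f'(100−x) = 100.

### Bootstrap confidence intervals

CIs are percentile bootstrap intervals with the **participant** as the
resampling unit — participants are the independent sampling units, and the
reported means are means across participants. For symmetrized conditions
each replicate also re-randomizes the A/B designation of every control
continuum before symmetrizing, so the interval reflects the arbitrariness
of the labeling. The same machinery, with one shared participant resample
feeding both curves, produces paired CIs for effect sizes (conditions are
within-participant in both designs). Percentile intervals (not BCa) are
used as the simplest method consistent with the design; default
`n_boot = 10_000` keeps the 2.5/97.5 percentiles stable, and every bootstrap
is seed-deterministic.

In a coverage study (15 participants × 50 Bernoulli(0.3) trials, 500 outer
simulations) the 95% percentile interval covers the true rate ~93% of the
time — the familiar mild undercoverage of the percentile method with 15
units; the acceptance band is 92–98%.

## Effect sizes and asymmetry bias

Per-level effects are raw percentage-point differences between two curves.
The sign convention is an explicit argument because both directions are
standard: blocked-design contrasts are conventionally reported as
reference-minus-condition, intermixed-design contrasts as
condition-minus-reference. Flipping the convention negates the table
exactly.

Within one condition with a meaningful familiar endpoint, the asymmetry
bias compares mirror-image morph pairs:

    bias(x) = f(x) − (100 − f(100−x)),  x ∈ {10, 20, 30, 40};
    bias(50) = f(50) − 50.

Negative values mean the familiar label is used conservatively. Any
symmetrized curve has bias identically zero (tested as a property).

## Mixed models

Both models share one fixed-effects structure — intercept, scaled morph
percentage (continuous), condition (zero-sum/effect-coded contrasts), and
the morph × condition interaction — and crossed random intercepts for
participant and continuum. Morph scaling defaults to z-scoring over trials
(center ≈ 50, scale ≈ 25.8 for the balanced nine-level design);
`center50_div40` is available. The scaling center/scale are stored on the
fit so boundaries can be mapped back to morph-percent units. The exact
zero-sum basis for the condition factor is cosmetic: Type-3 Wald statistics
are invariant to it (tested by permuting the level order).

### Binomial GLMM (choices)

Bernoulli trials are first aggregated to binomial counts per
(participant, continuum, condition, level) cell — the likelihood is
unchanged and the working data shrink from ~10⁴ rows to a few hundred.
The marginal likelihood integrates the random intercepts u out of the
logit model; we approximate it by the Laplace method:

* **inner step** — penalized IRLS (Newton with step-halving) for the joint
  mode of (β, u), with ridge precision 1/σ_f² on each factor's intercepts;
  convergence when the penalized log-likelihood changes by < 1e−10
  (relative).
* **outer step** — Nelder–Mead over the log standard deviations
  (bounds [−6, 2.5], start log 0.5), warm-starting the inner solve at the
  previous mode. The profiled Laplace objective is

      ℓ(θ) = log f(y | β̂, û) − ½ û'D û + ½ log|D| − ½ log|Z'WZ + D|,

  with D the prior precision and W the binomial IRLS weights at the mode.

On a small instance (3 participants, one continuum) the Laplace
log-likelihood agrees with exact Gauss–Hermite quadrature to < 0.1 (the
test oracle integrates each participant's intercept on 101 nodes). With
zero true random variance the fit collapses to plain logistic regression
(coefficients and standard errors match an independent GLM fit to < 1e−3).
β's covariance is the Schur complement of the joint Hessian at the mode,
i.e. conditional on the estimated variance components, matching standard
GLMM software. Coefficients exceeding |25| on the scaled predictors are
flagged as separation and the fit marked non-converged.

### Linear mixed model (log RTs)

RTs are log-transformed; the Gaussian random-intercept marginal likelihood
is exact. All likelihood evaluations use precomputed cross-products
(X'X, Z'Z, Z'X, Z'y, …), so each costs O(q³) with q ≈ 21 random
coefficients; Nelder–Mead runs over (log σ_participant, log σ_continuum,
log σ_resid) with β profiled by GLS inside. Fitting is by ML (not REML),
consistent with the Wald inference used downstream. Random factors with
fewer than two observed levels are dropped with a diagnostic, falling back
to OLS when none remain.

### Type-3 Wald tests and PSE

For each term with coefficient block b and covariance block V the statistic
is b'V⁻¹b on df = block size (for one-df terms this is exactly (b/se)²).
Wald rather than likelihood-ratio chi-squares are used, matching the
default of the standard analysis-of-deviance routine for mixed models.

The point of subjective equality for condition k solves
intercept + cond_k + (slope + interaction_k)·x = 0 with random effects at
zero, mapped back through the morph scaling; standard errors come from the
delta method, and boundary *shifts* against a reference condition use the
joint gradient of both PSEs.

## Synthetic-data generator

The generator emulates the two designs' statistical structure:

* **blocked design (`exp1`)** — 15 participants, six shared continua
  (3 familiar-B + 3 control), 9 levels × 12 presentations each
  (9,720 trials), blocked by condition in six 108-trial blocks;
* **intermixed design (`exp2`)** — 15 participants, ten unique continua
  each (4 stranger–friend, 2 stranger–self, 2 friend–self,
  1 stranger–stranger, 1 friend–friend), 10 presentations per stimulus in
  ten intermixed 90-trial blocks (13,500 trials).

Choices follow a lapse-adjusted logistic:
P(B) = λ/2 + (1−λ)·expit(slope·(m − PSE_k) + u_i + v_c). The lapse is
symmetric by the standard psychophysics convention; λ = 0 recovers exactly
the model the GLMM fits. Defaults: slope 0.12 per morph-percent unit,
λ = 0.02, σ_participant = 0.5, σ_continuum = 0.3, control PSE 50 and a 5–7
unit shift toward the familiar endpoint elsewhere — values that place the
midpoint response and its condition gap in the range typical of familiarity
morph experiments.

No published generative model exists for the RTs; the inverted-U of mean
RT over morph level motivates a lognormal with location
rt_base_log + offset_k + gain·(1 − |m−50|/40), scale 0.35, truncated at
10 s. Defaults rt_base_log = 6.48 (≈ 650 ms), gain 0.2, and a condition
offset of 0.08 log units for the familiar blocked condition (≈ the 800 vs
742 ms contrast scale), 0.12 for stranger–stranger in the intermixed
design, which was the slow condition there.

Trial order within a block is shuffled under the constraint that the same
continuum never appears on consecutive trials (sequential sampling with
forced-majority completion and restart on dead ends). Order is recorded
for realism only; no analysis in the package depends on it.

What the generator does **not** emulate: sequential/adaptation effects,
left/right response mapping, per-identity idiosyncrasies beyond a single
continuum intercept, RT–accuracy coupling, and non-stationarity over
blocks. Passing calibration tests therefore show the estimators work under
the assumed model, not that real data satisfy that model.

## Calibration studies (sizes and conditions)

* **Parameter recovery** — 100 replicates of the blocked design with slope
  0.12, boundary shift 5, σ_participant 0.5 and *no continuum variance*;
  the estimated shift and RT offset must land within 3 estimated SEs of
  truth in ≥ 95 replicates. Continuum variance is excluded from this study
  deliberately: with only three continua per condition the condition
  contrast is confounded with the mean of three continuum intercepts, and
  six continua cannot identify σ_continuum, so no estimator can be expected
  to calibrate against that configuration. The generator's default
  σ_continuum = 0.3 is kept for realism in ordinary use.
* **Null calibration** — 500 replicates with no boundary shift and λ = 0
  (the model-faithful generator setting): the Wald interaction test must
  reject at α = 0.05 with empirical rate in [0.03, 0.08].
* **Bootstrap coverage** — 500 outer simulations as described above.

`scripts/acceptance.py` re-runs smaller versions of these studies
(50/300/400 replicates) together with the worked-example arithmetic; the
sizes are chosen so the whole script completes in a few minutes on one
core while keeping Monte-Carlo error well inside the tolerance bands.

## Known limitations

* The GLMM uses a single Laplace approximation (no adaptive quadrature);
  for the binomial cell sizes here (10–12 trials) the approximation error
  is far below the inferential noise, but very sparse designs would need
  more nodes.
* Random slopes are not implemented; the model space is exactly crossed
  random intercepts.
* The published chi-square statistics of the original experiments are only
  reproducible from the authors' raw trial data; an optional integration
  test consumes a local copy under `data/raw/` when present.
* Percentile bootstrap intervals mildly undercover with 15 participants
  (see above); BCa could be slotted in behind the same interface.
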