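# Methods

## Model

All beliefs are Gaussian over a single spatial coordinate in plain degrees
(angles are never wrapped; the targets of interest stay well inside ±90°,
so no circular statistics are used). A trial is: target ε_T → internal
estimate ε\* = ε_T + η, η ~ N(0, σ_T²) → posterior with mean
G·ε\* and variance G·σ_T², where G = 1/(1 + σ_T²/σ_P²) is the shrinkage
gain towards the prior mean. Sensory noise is additive and
stimulus-independent. A flat belief is encoded exactly as `sd = inf`
(precision 0), so the MLE is literally the flat-prior limit of the same
code path rather than a large-number approximation. Non-zero prior means
are supported by shifting coordinates, though the analyses only use
zero-mean priors.

Decision rules map the posterior to a response:

- **MLE** — ε\* itself.
- **MAP** — μ_POST; response SD about the regression line is G·σ_T,
  giving the parabola σ² = G(1−G)σ_P² with maximum σ_P/2 at G = 0.5.
- **PM** (posterior matching) — one draw from the posterior; total
  response variance G²σ_T² + Gσ_T² = (1−G²)σ_P² exactly.
- **AS** (adaptive sampling) — a draw restricted to
  μ_POST ± w₀σ̂ with σ̂² = σ_POST²/(1−σ_POST²/σ_P²). Algebraically
  σ̂ = σ_T, so the window widens exactly as the evidence degrades. The
  defining property of the rule is σ_AS ≡ σ_POST, i.e. the linear
  variance relation G = 1 − σ²/σ_P².
- **MAP_BOX** — MAP under a uniform box prior; the posterior is the
  likelihood truncated to the box, whose mode is the clipped ε\*.

### The within-window AS sampling law

The rule's definition fixes the window but not the distribution inside it.
The default here samples the **posterior truncated to the window**, which
interpolates naturally between MAP (window → 0) and PM (window → ∞);
uniform-within-window is available via `DecisionConfig(as_law="uniform")`.
The truncated law does not reproduce the variance relation exactly: its
residual SD sits between −4% (mid gains) and +11% (G → 1) of the
σ = σ_P√(1−G) curve with w₀ = 0.9. We accept the choice if the simulated
sweep stays within 15% of the curve, which it does over σ_T ∈ [1, 60]; the
uniform law violates the curve badly at high gain and is not asserted
against it. When the posterior is as wide as the prior (relative tolerance
10⁻⁶), the window diverges and the rule falls back to a full-posterior
draw — the correct limit for absent sensory evidence. With σ_T = 0 every
rule returns the target.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| σ_P (elevation) | prior width, deg | 11.5 | the value used throughout the simulations and recovered by the elevation model fits |
| σ_P (azimuth) | prior width, deg | ∞ | binaural cues are reliable; behaviour is MLE-like |
| σ_T | sensory noise SD, deg | per condition | swept 1–60 in 0.5° steps (119 conditions) in the gain–variance sweep |
| w₀ | AS window factor | 0.9 | the rule's stated constant |
| n per block | trials per regression | 1000 | enough that the slope SE is ≈ σ_res/(√n·SD(targets)) ≲ 0.01 |
| target range | uniform, deg | ±35 (blocks), ±90 (sweep) | the two simulated paradigms |

Monte-Carlo standard errors used in tests: slope SE = σ_res/(√n·SD(T));
SD-of-residuals SE ≈ σ/√(2n).

## Regression and exclusion

`fit_linear` minimises mean squared error of R = g·T + b in closed form;
σ_res is the root *mean* squared residual (population divisor n, matching
the definition used by the analysis; at n = 1000 this differs from the
n−2 divisor by ~0.1%, at n = 24 by ~4%). Biases are reported but never
propagated. Group-level exclusion removes, in a single pass, any gain more
than 3 sample SDs (ddof = 1) from the mean of its pool; pools are formed
per experiment × component (whether the original analysis pooled
components or conditions is not stated; this is our choice, and it is what
`regress_study` applies). With fewer than 3 results the rule warns and
keeps everything.

## Model fitting and comparison

Each rule's curve is linear in σ_P² in variance space: predicted
σ² = c(G)·σ_P² with c = G(1−G), 1−G, 1−G² for MAP, AS, PM. The default
estimator is the closed-form least squares σ_P² = Σc_iσ_i²/Σc_i²; an
alternative fit on the σ scale (`space="sd"`, also closed form since the
model is linear in σ_P there too) serves as a sensitivity check. r² and r
are computed between observed and predicted σ_res on the σ scale — the
axes on which such data are plotted. Correlations are compared with the
independent-samples Fisher r-to-z test by default; because the two
correlations share the observed data the independence assumption is
optimistic, so a dependent-correlation variant (Steiger's Z, requiring the
correlation between the two predictions) is provided behind
`method="steiger"`.

## Synthetic data

The generator emulates the two study designs so the pipeline runs without
the (undeposited) behavioural data:

- **SNR experiment** — 5 subjects × SNRs {+30, −6, −12, −18, −21} dB.
  Targets cycle a polar grid of 12 directions × eccentricities
  {14, 20, 27}° (36 locations; the source description of "24 locations" is
  internally inconsistent with 12 × 3). 72 trials in the +30 dB
  no-background condition, 24 otherwise. Elevation responses follow the AS
  rule with subject-specific σ_P ~ N(11.5, 1²) deg; azimuth responses are
  MLE-like scaled by a constant motor gain 0.9 (matching the ~10%
  undershoot typical of orienting movements — pure MLE would give gain 1).
- **SNR → σ_T map** — a logistic in dB with floor 4.5°, ceiling 20°,
  midpoint −14 dB and slope 5 dB (subject-jittered midpoint, SD 2 dB),
  chosen so elevation gains span ≈ 0.87 at +30 dB to ≈ 0.32 at −21 dB.
  This map is pure fixture plumbing: monotone, bounded, four parameters.
- **Low-pass experiment** — 7 subjects × 100 trials; targets uniform over
  the frontal hemifield under the double-pole constraint
  |azimuth| + |elevation| ≤ 90°; elevation responses are prior-only draws
  (no spectral cues → σ_T = ∞), azimuth high-gain.

What the generator does **not** emulate: reaction times and movement
kinematics, audio-visual interactions, per-trial adaptation or learning,
heteroscedastic (eccentricity-dependent) noise, and any acoustic front-end
(HRTFs, spectral correlation). Passing tests therefore demonstrate that
the *pipeline* recovers the generative structure it assumes, not that real
listeners obey it.

### Pooling in the headline comparison

The end-to-end analysis (`soundloc.pipeline.run_study_analysis`) pools the
elevation (gain, σ_res) points of the SNR **and** low-pass experiments
(32 points) before fitting the three curves. Pooling is essential for
identifiability: over the gain range the SNR conditions alone produce
(≈ 0.3–0.9), the AS and PM curves with a free σ_P are nearly proportional
and r² cannot separate them, whereas the low-pass points at gain ≈ 0 pin
both curves' common intercept at σ_P. On the default seed the pipeline
recovers σ_P = 11.5° under AS (within 10% across seeds; a residual ≈ 5%
downward bias traces to the divide-by-n residual SD at 24-trial cells plus
the truncated AS law sitting slightly below its curve at mid gains) and
ranks AS > PM > MAP by r², with MAP's r² strongly negative — the
non-monotone parabola cannot follow a monotone negative gain–variance
relation.

## Numerical choices

- Every stochastic operation takes an explicit `numpy.random.Generator`;
  sweeps and studies derive independent child seeds via `SeedSequence`, so
  any row is reproducible in isolation and identical configs are bitwise
  reproducible.
- Truncated-normal draws use `scipy.stats.truncnorm` with standardised
  bounds ±h/σ.
- Test tolerances for Monte-Carlo quantities are 3 standard errors. Where
  a check runs over all 119 sweep conditions at once, it asserts nominal
  coverage (≥ 97% of conditions within 3 SE, none beyond 5 SE) rather than
  a strict maximum, since an all-of-119 bound at 99.7% nominal coverage
  fails by chance in roughly a third of runs.
- Problem sizes throughout (1000-trial blocks, 119-condition sweeps,
  study-sized synthetic cohorts) keep the full test suite and the
  acceptance script in the seconds-to-a-minute range on one CPU.

## Known limitations

- The AS within-window law is a documented choice, not a derived result;
  other laws inside the same window satisfy the rule's definition to
  different accuracy.
- The Fisher comparison treats model correlations as independent; use the
  Steiger variant when the shared-data dependence matters.
- σ_P recovery inherits the small-sample biases noted above; at study
  sizes expect a few percent, not exactness.
- Azimuth and elevation are simulated as independent channels; coupled 2-D
  response models are out of scope.
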