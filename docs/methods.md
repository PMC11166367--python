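# Methods

This note documents the models, algorithms and numerical choices behind
the package, and what its synthetic-data validation does and does not
demonstrate.

## The fatigability score

Performance fatigability is the decrement in performance during a
standardized task — here, the decline in walking cadence over a
usual-paced 400-m corridor walk (10 laps of 20 m). From a
cadence-versus-time trajectory `c(t)` on `[0, T]` (T = accelerometer-
covered walk time), the score is an area ratio:

```
PPFI = 100 * (1 - AUC_obs / AUC_max),
AUC_obs = ∫ c(t) dt,   AUC_max = max_t c(t) * T
```

A walker who never slows scores 0; higher scores mean steeper or
earlier decline. Walkers who finish the 400 m within 6 minutes (360 s,
boundary inclusive) show negligible decline and are assigned 0% by
rule; the rule is applied after scoring and overrides the computed
value, with the flag preserved for audit. Severity strata use
sex-specific cut-points: none (score = 0), mild (0 < score < 3.5% for
women, < 5.4% for men), moderate-to-severe (≥ 3.5% / ≥ 5.4%,
boundary inclusive).

Two robustness choices: the maximal cadence is taken from the
*smoothed* curve, so one noisy window cannot inflate `AUC_max`; and
negative fitted values are clamped to 0 before integration. The walk
duration entering both areas is the accelerometer-covered time; the
stopwatch completion time governs only the 6-min rule. Integration is
trapezoidal on the 1-s grid (error O(Δt²), negligible at 1 s).

## Cadence extraction

The wrist device records triaxial acceleration at 80 Hz. Processing:

1. Vector magnitude √(x²+y²+z²); subtract its 5-s rolling median
   (gravity and slow orientation drift).
2. Band-pass 0.4–3.0 Hz, 4th-order Butterworth applied forward and
   backward (zero phase).
3. Sliding 6-s window, 1-s hop, centred on each grid second: the
   dominant periodogram frequency in 0.4–1.5 Hz is the arm-swing
   (stride) rate; cadence = 120 × f since one arm swing spans two
   steps. The FFT is zero-padded 32× so the frequency quantization
   (~0.005 Hz, ~0.6 steps/min) is well below the accuracy target.
4. Quality flag: a window is flagged when less than half of its band
   power lies within ±0.1 Hz of the peak (no clear oscillation); the
   first/last 3 s are always flagged (start/stop and turn transients).
   Flagged points are linearly interpolated from unflagged neighbours;
   more than 50% flagged raises an "unreliable cadence" error.

A 6-s window holds ≥ 5 stride cycles at usual cadence — long enough
for a sharp spectral peak, short enough that within-window cadence
drift (< 0.5 steps/min for realistic declines) is negligible. The
search band 0.4–1.5 Hz is also what disambiguates the stride
fundamental from its first harmonic. The estimator is invariant to
amplitude scaling and equivariant to time shifts by construction.
The published index derives cadence with a different (step-detection)
algorithm whose details live outside this package; the spectral
estimator here is a stand-in validated against synthetic ground truth
(pooled RMSE < 3 steps/min, bias within ±1 steps/min over random
profiles), not a re-implementation of that algorithm.

## Penalized-spline smoothing

The cadence series is smoothed with P-splines: a cubic B-spline basis
with one interior knot per 10 s (minimum 8 basis functions) and a
second-order difference penalty on the coefficients. For each λ on a
41-point log grid 1e-4…1e6, coefficients solve
`(B'B + λD₂'D₂ + 1e-9·I)θ = B'y` on the unflagged points; λ minimizes
the GCV score `n·RSS/(n − edf)²` with `edf = tr[(B'B+λD₂'D₂)⁻¹B'B]`.
The tiny ridge guards basis regions emptied by flag exclusions. The
penalty null space contains straight lines, so noiseless linear
trajectories are reproduced exactly at any λ; a constant series
returns a constant fit rather than an error.

## Left-censored (tobit) regression

The score is bounded below at 0 with a point mass there (35.6% of the
emulated cohort), so associations with muscle energetics use a latent
Gaussian linear model `y* = x'β + ε`, observed as `y = max(0, y*)`:

```
l(β, σ) = Σ_{y=0} log Φ(−x'β/σ) + Σ_{y>0} [log φ((y−x'β)/σ) − log σ]
```

maximized in `(β, log σ)` by BFGS with the analytic gradient from an
OLS start, followed by Newton polishing with the numerical Hessian
until the gradient ∞-norm is < 1e-6 (BFGS alone stalls slightly above
tolerance because covariate columns — age, activity counts — are on
very different scales); up to five jittered restarts. The coefficient
covariance is the inverse observed information; CIs are β ± 1.96·se.
Censored-term log-probabilities and inverse Mills ratios are computed
in log space so deep-tail terms stay finite. With no censored rows the
MLE coincides with OLS (tested to 1e-4); the full fit is cross-checked
against R's `survival::survreg` (left-censored gaussian) in the test
suite. Only left-censoring at 0 is modelled; no right-censoring at 100
(observed scores stay far below it).

Variance explained uses the McKelvey–Zavoina latent-scale R²,
`var(x'β̂)/(var(x'β̂)+σ̂²)`, the standard definition for censored
outcomes; the partial R² of an exposure is
`(R²_full − R²_reduced)/(1 − R²_reduced)`, floored at 0, with the
reduced model refit on identical rows. Other pseudo-R² definitions
(Cox–Snell-type, squared partial correlation) would give different
numbers; this choice is an interpretation, not a reproduction of any
published value.

## Proportional-odds model and Brant–Wald test

Severity strata are modelled with a cumulative-logit proportional-odds
model (one common slope across the J−1 cut-points), maximized through
statsmodels' `OrderedModel` (BFGS at gtol 1e-7, Newton fallback; at
J = 2 it agrees with binary logistic regression to 1e-8). Exposures are
standardized and sign-flipped before fitting, so `exp(β)` is the odds
ratio of a *worse* stratum per 1 SD lower energetics — OR > 1 means
lower energetics, worse fatigability.

The proportionality assumption is checked with the Brant–Wald test:
fit the J−1 binary logits of I(y > j), stack the slope vectors, build
their joint covariance from Brant's moment formula
(`cov(β̂_j, β̂_l) = (X'W_jj X)⁻¹ (X'W_jl X) (X'W_ll X)⁻¹` with
`W_jl = diag(π̂_l − π̂_j π̂_l)`), and test equality of each predictor's
slopes across logits: χ² with (J−2)·p df. Fewer than 10 observations
in any outcome level triggers an instability warning; separation in
any sub-model raises a diagnostic error. The test is a diagnostic —
it has no published value to match — and its size is verified by
simulation from a proportional-odds null (rejection ≈ 5% at α = 0.05).
Note that strata derived from a latent-*normal* score follow a
cumulative-probit law, so on this package's own censored-normal
generator the logit-scale Brant test is mildly misspecified and
rejects somewhat above nominal; that is a property of the generator,
not a test-size defect, which is why the calibration study simulates
from the proportional-odds model directly.

## Cohort analysis conventions

* Model tiers accumulate covariates: Model 1 — technician/site
  indicators, age, sex, race; Model 2 — + height, weight; Model 3 —
  + total activity count. Height and weight enter separately (BMI is
  descriptive only).
* Complete-case per exposure: subjects missing an exposure are
  excluded only from that exposure's models; exposure z-scores are
  computed on the complete cases, and the standardizing SDs are
  reported alongside so effects can be read on the raw scale.
* Descriptive table: pre-declared test families (a configuration
  choice, not a runtime normality decision — reproducibility):
  median [IQR] + Kruskal–Wallis for the score and energetics;
  mean ± sd + ANOVA for age, height, weight, SPPB, activity count;
  n (%) + chi-square for sex and race (binary analytic coding).
* Spearman correlations use mid-ranks with the t-approximation p.
* Interactions: exposure × sex and exposure × physical function
  (SPPB ≥ 10 vs < 10) product terms added to Model 3, Wald p at
  α = 0.05 two-sided; function-stratified Model-3 fits (SPPB is not a
  Model-3 covariate, so stratification needs no covariate change); a
  stratum with fewer than p + 5 rows is skipped with a warning.
* No multiplicity adjustment anywhere, matching the emulated design.

## Synthetic-data generators

**Walk signal.** The wrist oscillates once per stride (two steps), so
the gravity-aligned axis carries
`1 + A·[sin(2π∫c(t)/120 dt) + ½·sin(4π∫c(t)/120 dt)]` (fundamental at
the arm-swing frequency plus a first harmonic at half amplitude,
default A = 0.25 g), Gaussian sensor noise (sd 0.05 g) on all axes,
and a 0.4-s half-sine bump (0.4 g) on a transverse axis at every 20-m
lap turn. Placing the oscillation on the gravity axis keeps the
vector magnitude linear in the swing (|1+s| ≈ 1+s for |s| < 1); on a
transverse axis the magnitude nonlinearity would move the dominant
oscillation to twice the swing frequency. The recording stops when
integrated distance `∫ c/60 · step_length dt` reaches 400 m; the
crossing time is the stopwatch completion time. Default profile:
linear decline 108 → 96 steps/min over 400 s with 0.62-m steps
(average speed ≈ 1.05 m/s, a typical usual-paced older-adult walk,
finishing in ~6.3 min). What the generator does *not* emulate:
step-to-step timing variability, asymmetric arm swing, posture
changes, device re-orientation, or non-walking segments — so passing
extraction tests show the estimator recovers oscillatory cadence
under noise and turn artifacts, not that it handles every failure
mode of real wrist data.

**Cohort.** Latent score
`PPFI* = μ + β·(−z_exposure) + Σ γ_k z_k + ε`, observed
`PPFI = max(0, PPFI*)`, strata via the sex-specific cut-points.
Defaults: μ = 1.4, marginal latent SD σ = 1.4/|Φ⁻¹(0.356)| ≈ 3.7923 —
the unique latent normal whose censored outcome has a 35.6% zero mass
and median 1.4% (with under half the mass censored, the observed
median equals the latent median). The residual sd is derived as
`√(σ² − β² − Σγ²)`, so the calibration holds for any effect size. One
latent normal cannot also match the printed 75th percentile (2.9%):
matching zero-mass and median is the documented choice, and the upper
tail of the synthetic score is accordingly lighter than the real one
(real max 21.7%). Effect default β = 0.55% per 1 SD lower primary
exposure; covariate effects default to 0 so recovery studies isolate
the exposure path (configurable). Exposures are drawn independently
by default (configurable common correlation); means/SDs 56.9/18.4,
77.0/22.1, 0.51/0.15 on the three energetics scales; covariates match
the emulated cohort's summaries (age 76.4 ± 5 truncated to [70, 94],
58.1% women, 86% white, SPPB rounded-normal 10.2 ± 1.8 clipped to
0–12, activity count 198 ± 58, 2 sites × 2 technicians uniform).
Missingness is MCAR per exposure at 13.5%/29.3%/6.7%. A single
`numpy` Generator seeded per simulation makes outputs bit-identical
under a fixed seed.

## Study sizes used in validation

Parameter recovery: 500 cohorts of n = 795 (mean Model-3 estimate
within 2 Monte-Carlo SEs of the generating 0.55; CI coverage within
[0.93, 0.97]). Calibration: one cohort of n = 50,000. Extraction
accuracy: 100 random walk profiles. Test-size calibration: 500
simulated datasets per test at n = 795. Score bounds: 1,000 random
trajectories. These sizes give Monte-Carlo SEs of ~0.007 on the
recovery mean and ~1 percentage point on rejection rates.

## Known limitations

* The cadence estimator is a spectral stand-in for the published
  step-detection pipeline; agreement with it on real data is untested.
* The 6-s window cannot follow cadence changes faster than ~0.5 Hz/s;
  abrupt stops within a walk blur into neighbouring windows.
* The latent-normal outcome matches only the zero mass and median of
  the real score distribution, not its heavy right tail.
* Normal-based CIs and the observed-information covariance assume a
  correctly specified homoscedastic latent model; no robust or
  clustered standard errors are provided.
* The Brant–Wald implementation requires each binary sub-model to be
  estimable; heavy separation raises an error rather than a penalized
  fallback fit.
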