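# fatigability

Performance-fatigability analysis for aging research: compute the
Pittsburgh Performance Fatigability Index (PPFI) from raw wrist
accelerometry recorded during a usual-paced 400-m walk, classify its
severity, and estimate how skeletal-muscle energetics (maximal
OXPHOS, electron-transfer-system capacity, ATPmax) relate to it with
the censored-outcome and ordinal models the index calls for. A
synthetic-data generator with known ground truth stands in for
restricted cohort data, so every stage — signal processing, spline
smoothing, scoring, regression — is testable at desk scale.

Intended for epidemiologists and mobility researchers who have (or
emulate) 80-Hz wrist recordings of a timed 400-m walk plus a
per-subject covariate table.

## The score and the models

From a smoothed cadence trajectory c(t) over the walk time T:

```
PPFI = 100 · (1 − ∫ c(t) dt / (max c · T))      (percent, 0–100)
```

Higher = more severe fatigability; completing 400 m within 6 min
scores 0% by rule. Severity strata: none (0%), mild, and
moderate-to-severe (≥ 3.5% women / ≥ 5.4% men). Cadence comes from the
dominant 0.4–1.5 Hz spectral peak of the band-passed wrist
acceleration magnitude in sliding 6-s windows (cadence = 120 × arm-
swing frequency); smoothing is a penalized cubic regression spline
(second-difference penalty, GCV-chosen λ).

Because PPFI is left-censored at 0 (a third of a typical cohort shows
no fatigability), continuous associations use tobit maximum
likelihood, `y* = x'β + ε`, `y = max(0, y*)`, with McKelvey–Zavoina
partial R²; severity strata use cumulative-logit proportional-odds
regression with the Brant–Wald proportionality diagnostic. Exposures
are standardized and sign-flipped, so every β or OR reads "per 1 SD
*lower* energetics". Covariates accumulate over three model tiers
(site/technician, demographics → + height/weight → + activity count).

See `docs/methods.md` for the full model and numerical details.

## Worked example

```python
import fatigability as fg

# one synthetic 400-m walk with a declining cadence (108 -> 96 steps/min)
recording, truth = fg.simulate_walk(fg.WalkProfile(seed=3))
cadence  = fg.extract(recording)                     # 80-Hz signal -> steps/min
smoothed = fg.smooth_trajectory(cadence)             # penalized spline
result   = fg.compute_ppfi(smoothed, recording.completion_time_s)
result.stratum = fg.classify_severity(result.score, recording.sex)
print(f"completion time : {recording.completion_time_s:.1f} s")
print(f"max cadence     : {result.max_cadence:.1f} steps/min")
print(f"PPFI score      : {result.score:.2f} %")
print(f"stratum         : {result.stratum}")
```

```
completion time : 378.3 s
max cadence     : 108.3 steps/min
PPFI score      : 5.50 %
stratum         : moderate_to_severe
```

The walk took 6.3 min (no zero rule), peak smoothed cadence was 108.3
steps/min, and the area under the observed trajectory fell 5.50%
short of the no-fatigue rectangle — above the 3.5% female cut-point,
hence moderate-to-severe.

Cohort side: simulate 795 subjects under the calibrated defaults and
fit the fully adjusted models for the OXPHOS-like exposure:

```python
df  = fg.simulate_cohort(fg.default_params(n=795, seed=1))
seq = fg.run_model_sequence(df, "max_oxphos", tiers=(3,))
print(seq.tidy()[["model", "n", "beta", "ci_lo", "ci_hi", "or"]].round(3))
```

```
 model   n  beta  ci_lo  ci_hi    or
     3 687 0.542  0.233  0.851 1.233
```

Each 1 SD lower exposure raises the latent score by 0.542% (95% CI
0.233–0.851) — the generator's true effect is 0.55 — and the odds of
a worse severity stratum by 23%. n = 687 because 13.5% of this
exposure is missing-at-random and models are complete-case per
exposure.

The same stages are scriptable from the shell:

```
fatigability simulate walk --seed 3 --out walkdir/
fatigability extract --in walkdir/walk.csv --out cadence.csv
fatigability score --cadence cadence.csv --sex F --completion-time 378.3 --out result.json
fatigability simulate cohort --n 795 --seed 1 --out cohort.csv
fatigability analyze --cohort cohort.csv --out report/
```

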