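# Methods

This note documents the analysis pipeline implemented in `insolegait`:
the signal model, the defaults and why they hold, the numerical choices,
what the synthetic generator does and does not emulate, and the known
limitations.

## Signal model and preprocessing

The input is one foot's total vertical ground-reaction force sampled at
100 Hz (other rates are rejected rather than resampled). Missing samples
are carried as NaN end to end; they are never zero-filled, because a
zero is a valid force reading during swing.

**Stance segmentation.** A stance is a maximal run of samples with force
strictly above 30 N. Interior runs of at most 3 consecutive samples that
are missing or at/below threshold are bridged — short device faults and
momentary dips should not split a stance — but a stance can neither
start nor end on a bridged sample: its boundaries are genuinely loaded
readings. Events shorter than 300 ms or longer than 3500 ms are dropped
as non-stride activity (both bounds inclusive). Bridged samples keep
their recorded values when present; missing ones are linearly
interpolated so the grid stays uniform for the filter and the spline.
The bridge rule treats sub-threshold dips and device faults alike; this
is deliberately symmetric and is the natural reading when only total
force is available.

**Normalization.** Three steps, in this order:

1. Gaussian filter, σ = 4 *samples* (40 ms at 100 Hz), reflect boundary
   handling, kernel truncated at 4σ (truncation error < 1e-4 of kernel
   mass). Smoothing runs on the raw grid, where σ has physical meaning,
   not on the duration-normalized grid. σ is interpreted in samples; an
   interpretation in milliseconds would coincide at 100 Hz anyway up to
   the stated factor of 10. Reflect padding avoids edge droop on short
   stances.
2. Conversion to percent bodyweight: 100 · F / (m · g) with
   g = 9.81 m/s².
3. Natural cubic spline (zero second derivative at the ends) through
   (i, yᵢ), evaluated at 100 equidistant abscissae spanning the event.
   At least 4 input samples are required; shorter events are dropped and
   logged. Spline overshoot below zero is possible and preserved — only
   finiteness is asserted on the normalized arrays.

Both a *filtered* and an *unfiltered* variant of the 100-sample curve
are kept. All shape detection (extrema, inflections) runs on the
filtered signal; all force values are read off the unfiltered signal at
the detected indices, so magnitudes are not biased by the smoothing.
Indices are 0-based internally (0…99); index i maps to absolute time
`stance_start + (i/99) · duration`.

## Landmarks and the regularity label

**Extremum candidates** are strict interior sign changes of the first
difference; a plateau of equal values yields its centre index once.

**Enclosing turning points** TP1/TP2 are the first and last inflection
points: sign changes of the central second difference
d2ᵢ = yᵢ₊₁ − 2yᵢ + yᵢ₋₁ over the interior indices. A sign change between
two interior points is attributed to whichever of the two has the
smaller |d2| (nearest the true zero crossing). Curvature below 1e-9 of
the signal scale counts as zero, so affine signals produce no spurious
crossings from float noise. Fewer than two sign changes → the turning
points are absent and the TP-based parameters are omitted downstream.

**Disambiguation cascade.** The M-shape criterion — two unambiguous
local maxima with a single local minimum in between — is tested on the
raw candidates first; on failure three strategies are applied in order,
to maxima and minima alike, re-testing after each and stopping early:

1. *Cluster merge*: candidates within 5 % of the time span (5 index
   units, inclusive, chained) merge; the highest (maxima) or lowest
   (minima) member survives.
2. *Dominance*: within one half of the stance (indices 0–49 vs 50–99), a
   candidate exceeding every other candidate in that half by a factor of
   1.05 (inclusive at exactly 1.05) suppresses the others.
3. *Monotony*: candidates whose flanks are not weakly monotone over 5
   samples on both sides (clamped at the array bounds) are eliminated.
   Weak monotonicity keeps plateau shoulders from being spuriously
   removed.

The M-criterion itself requires: exactly two maxima; strictly between
them exactly one minimum candidate, which must also be the lowest
filtered value of the open interval; and each maximum must exceed that
minimum by the same 1.05 factor used in strategy 2. The last clause
makes "unambiguous" operational: without it, a flat plateau whose
residual filtered noise forms two ripples a couple of percent above
their valley would count as an M-shape, which contradicts the premise
that plateau stances are non-regular. The factor is scale-invariant, so
the label does not depend on bodyweight normalization.

A stance is labelled *regular* iff the cascade resolves; the per-visit
*regular ratio* is the fraction of regular stances. For non-regular
stances with at least two surviving maxima, the first/last maximum
indices are still recorded: the inter-max parameter family is computed
for regular strides *and* non-regular strides with more than one
maximum, and omitted only for single-maximum stances.

## The twelve parameters

Forces in %BW, times in seconds, normalized times in % of stance
duration; trendline slopes in %BW per % stance duration (the regressor
is the 100-sample index).

| family | parameters | availability |
|---|---|---|
| force read-off | `F_total_max`, `F_mean_TP` | always / TPs present |
| trendline (max) | `F_trendline_max_slope`, `L1_trendline_max`, `L2_trendline_max` | > 1 maximum |
| trendline (TP) | `F_trendline_TP_slope`, `L1_trendline_TP`, `L2_trendline_TP` | TPs present |
| timing (max) | `Time_inter_max`, `Time_inter_max_normalized` | > 1 maximum |
| timing (TP) | `Time_inter_TP`, `Time_inter_TP_normalized` | TPs present |

`F_mean_TP` is the mean of the unfiltered curve over the inclusive index
range [TP1, TP2]; the divisor is the sample count TP2 − TP1 + 1. A
`strict_table1_denominator` switch restores the span divisor
TP2 − TP1 for comparison with conventions that treat the range as
half-open. `F_total_max` is read from the unfiltered curve — it is meant
as the raw highest force measurement, with no shape prerequisites.
Timings are reported as positive magnitudes; the normalized variants are
plain index spans (0–99 % stance). L1 is the MAE and L2 the RMSE of the
trendline residuals, so L1 ≤ L2 always.

## Aggregation and trend regression

Parameters are aggregated per measurement (visit) and leg side by the
arithmetic mean over the strides where each parameter is present. Before
cross-subject regression, each parameter is Min-Max normalized within
subject over all of that subject's measurements, both sides pooled (a
per-side scope is available as a sensitivity option); subjects with a
constant value are excluded for that parameter.

Four candidate relations are fitted against days after surgery, each as
a single-regressor transform g(x) ∈ {x, x², x³, ln x}, so that the null
hypothesis "slope = 0" is a one-parameter Wald t-test with df = n − 2
(two-sided). The fit itself uses an iterative least-squares optimizer
capped at 500 evaluations; a non-converged relation is discarded (for
these linear-in-parameters models the iterative fit coincides with the
closed-form OLS solution to ≤ 1e-6, which is asserted by test). The
logarithmic relation requires all x ≥ 1 and is skipped otherwise.
Full multi-term polynomial fits are intentionally not the default: they
would not admit a single-slope Wald test. Relations with p ≥ 0.05 are
discarded (no multiple-testing correction is applied); among the
survivors the relation with the lowest residual sum of squares wins,
ties broken by higher R². A parameter–side pair with no significant
relation is reported as absent, not as its best insignificant fit.

The regular ratio gets a dedicated protocol: OLS of ln(ratio) on days
after surgery per side. Visits with ratio 0 are excluded by default
(ln 0 undefined); an epsilon policy (+1e-3) is available by
configuration. This exclusion biases the fitted slope toward zero when
early-recovery visits with few strides often draw zero regular strides —
see Limitations.

## Synthetic data

`make_stance_curve` builds one stance from raised-cosine segments
between control points, so every control point is an exact local
extremum with zero slope — true landmark positions are known in closed
form. Shapes: `m_shape` (two bumps and a valley), `plateau` (trapezoid
with linear ramps), `single_hump`. Gaussian noise (in %BW) and
per-sample dropout (NaN) are applied last; forces are clipped at 0 N.

`make_cohort` emulates the study conditions: 13 subjects, 3–7 visits
each — one early visit (days 3–10) plus follow-ups spread over days
14–175 — body mass ~ N(75, 12) kg, and 8–15 strides per foot and visit
(a ~9 m straight walk). Per visit and side, each stride is drawn regular
with probability p(d) = min(1, exp(a + b·d)); the defaults
(a, b) = (−3.18, 0.02) for the healthy and (−2.38, 0.014) for the
injured side are the log-linear ratio models the method reports on real
recovery data, reused as generator truth. Morphology trends move the
injured side's M-shape peaks from ~72 to ~110 %BW and its plateau height
from ~45 to ~85 %BW over 175 days, with mild per-stride jitter; default
sensor noise is 3 %BW with dropout probability 0.002. The generator is
fully deterministic under a fixed integer seed.

What the generator does **not** emulate: center-of-pressure or
per-sensor (16-cell) pressure data, temporal sensor drift, walking aids,
cadence/speed structure within a bout, inter-stride correlation, and
non-gait load events. Passing tests on synthetic cohorts therefore
demonstrate the correctness and statistical behaviour of the pipeline
under the stated model, not clinical validity on patient data.

## Numerical and scale choices

* Problem sizes used in the tests and the acceptance script — 1000
  random traces for the segmentation oracle, 200 smooth curves for the
  turning-point oracle, 500 noisy curves for classification robustness,
  and 100 (tests) / 50 (script) replicate cohorts for trend recovery —
  were chosen so each check runs in seconds to a couple of minutes on a
  single CPU while keeping Monte-Carlo error well below the asserted
  margins.
* Threshold comparisons are strict (> 30 N): a constant 30 N trace
  yields no event. Duration bounds are inclusive.
* The dominance factor is applied inclusively (ratio ≥ 1.05 counts as
  "exceeded"), keeping the rule effective at exactly the printed
  constant.
* Ties in best-relation selection are broken deterministically by
  higher R²; classification and the whole pipeline are deterministic
  given input and config.

## Limitations

* The ln(regular-ratio) slope estimated from visits with 8–15 strides is
  attenuated relative to the generating slope: excluding zero-ratio
  visits truncates the left tail early in recovery, ln of a binomial
  proportion is biased downward where p is small, and the
  min(1, exp(·)) cap flattens the late end. A pure binomial simulation
  (no signal processing) shows the same ≈ 20–25 % attenuation on the
  healthy side, so this is a property of the estimator under the study
  design, not of the signal pipeline; the pipeline itself reproduces the
  drawn per-visit ratios essentially exactly.
* Classification of genuinely ambiguous stances depends on the 1.05
  contrast convention; curves whose peak-to-valley contrast sits near
  5 % will flip labels under small noise.
* `Gradient_loading_slope` / `Gradient_unloading_slope`-style loading-
  edge parameters are out of scope (no printed definition to implement),
  as are COP-based and asymmetry (PPD/PCI) indices and sensor-drift
  correction.
* The regression layer models each parameter separately against days
  after surgery; no subject-level random effects or additional
  covariates are included.
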