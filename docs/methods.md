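# Methods

## Problem and model

The package quantifies how the daily peak (acrophase) of hourly relative
search volume (RSV) moves when the civil clock shifts by ±60 minutes at a
Daylight Saving Time transition. RSV is a 0–100 integer rescaling of
search frequency within a delivery window; absolute volumes are never
observed, and each 7-day window carries its own private scale. The
analysis chain is: stitch windows onto one scale → fit a daily rhythm →
filter unreliable days → compare circular mean phases across the
transition → (optionally) test for drift across years.

All timestamps are UTC. The civil-time rule is hard-coded to Italy
(CET = UTC+1, CEST = UTC+2, switching at 01:00 UTC on the last Sunday of
March/October); other zones are out of scope.

## Stitching

Consecutive windows overlap by exactly two calendar days (48 hourly
points). The normalization coefficient for window *k* is the ratio of the
overlap sums,

    c_k = Σ(normalized values of window k−1 on the shared days)
          / Σ(raw values of window k on the shared days),

chained multiplicatively back to the first window (c₁ = 1). Design
choices, each genuinely open:

* **Sum ratio, not mean of pointwise ratios.** Night hours of low-volume
  terms are frequently 0–1 RSV units; pointwise ratios explode there. The
  explicit least-squares ratio Σ(ref·inc)/Σ(inc²) is kept as a test
  oracle only; on realistic overlaps the two agree within 2%.
* **Earlier values win on shared days.** The incoming window's overlap is
  used only to estimate c_k, keeping the series single-valued and
  avoiding double-counting.
* **Zero-sum overlap is an error**, not a silent c = 1: it means the data
  are too sparse to stitch at all.

With no rounding the reconstruction is exact (verified to 1e-12); with
max-100 integer quantization the residual error stays ≤ 2% after one
global rescale.

## Daily rhythm fit

Each calendar UTC day (24 points) is fitted with a single-harmonic
cosinor, the standard chronobiology model when the period is known:
y_t = M + A·cos(2π(t − φ)/24), solved through the linear parameterization
in cos/sin with A = √(β₁²+β₂²), φ = atan2(β₂, β₁)·24/2π mod 24. The
original study used proprietary, undocumented fitting software whose
outputs were a peak phase, a fit significance, a fit-vs-data Pearson r and
a Rhythmicity Index; the cosinor produces all four natively and is the
central documented substitution of this package.

* **Significance**: the classical zero-amplitude F test,
  F = (SS_model/2)/(SS_residual/(n−3)), p from F(2, n−3). On flat
  Gaussian-noise days the test is exactly calibrated (type-I error ≈ 5%
  at α = 0.05, verified over 1,000 simulated days).
* **Rhythmicity Index**: RI = r × 2A. "Regression coefficient" is read as
  the Pearson correlation between fit and raw data — the only
  correlation-like quantity defined alongside the index — and the "range
  of oscillation" as the fitted peak-to-trough 2A (robust to noise,
  unlike raw max−min).
* **Degenerate days**: constant input yields amplitude 0, undefined (NaN)
  acrophase and p = 1, so the significance filter removes such days
  rather than erroring.
* **Day boundary**: calendar UTC days. The cosinor phase is circular
  within the day, so peaks near midnight are estimated without bias at
  the day edge; no sliding window is needed.
* **Boundary convention**: days with p exactly equal to α are retained
  (removal applies to p strictly above the threshold).

Shifting a day's values circularly by k hours shifts φ by exactly k
(mod 24) and changes nothing else; scaling by c > 0 scales A, 2A and RI
by c and leaves φ, r and p untouched — both verified as property tests,
along with agreement of φ with an exhaustive profiled grid search to the
grid resolution (0.01 h).

## Phase statistics

Acrophases live on a 24-h dial, and several analysed terms peak near
midnight, so all averaging is circular:

* **Means** are vector circular means. For interval statistics the phases
  are first *unwrapped* about a reference (each mapped to its unique
  representative in (ref−12, ref+12]).
* **Outliers**: Tukey's boxplot rule, fences at Q1 − 1.5·IQR and
  Q3 + 1.5·IQR with linearly interpolated quartiles, applied to the
  phases unwrapped about their circular mean so that a tight cluster
  straddling midnight is never split into two false groups. Points
  exactly on a fence are kept ("outside the whiskers" read strictly).
  Fewer than four points: quartiles are not meaningful, the filter is
  skipped with a logged notice. Note that on very tightly clustered
  phases (IQR of a few minutes) the rule is intentionally strict and can
  trim days whose phase error is only slightly larger than the rest.
* **Pre/post comparison**: classic equal-variance two-sample Student
  t-test (not Welch) on both sides unwrapped about their pooled circular
  mean; the signed difference (post − pre) is wrapped to (−720, 720]
  minutes, negative = advance. With fewer than two phases on a side the
  p-value is reported as NaN.
* **Combined-years rows** pool all retained daily phases across years
  (not the mean of yearly means), matching a single reported pre/post
  phase per word and season.
* **Year trend**: the study described a repeated-measures ANOVA with
  phase as fixed and time as random factor, which is internally odd as
  stated; implemented instead as (a) a one-way ANOVA with year as the
  factor on unwrapped daily phases and (b) a least-squares regression of
  phase on year, slope reported in minutes/year with its t-test p. Both
  are reported rather than guessing the original's exact design.

The analysis windows are 15 whole UTC days per side; the transition day
(whose 01:00 UTC switch leaves 23 of 24 hours post-transition) is the
first post day.

## Synthetic generator

The generator emulates exactly the features the analysis relies on:

* cosine intensity `max(0, [B + A·cos(2π(clock(t) − φ)/24)]·w^{weekend}·spike + ε)`
  with the acrophase anchored to local civil time;
* the **social coupling fraction** s ∈ [0, 1]: after the transition the
  UTC acrophase moves by exactly s·60 min (spring: advance; autumn:
  delay). s = 1 is fully social-clock-driven behaviour, s = 0 fully
  solar/endogenous. The exact per-day UTC acrophase is returned as ground
  truth;
* weekends (Saturday/Sunday in local civil time) multiply the level by
  `weekend_gain`; optional one-day event spikes (e.g. a Halloween surge)
  multiply one local day;
* additive Gaussian noise on intensity (not Poisson counts — RSV is
  already an aggregate ratio and a count scale is unobservable), clamped
  at 0;
* the observation model: 7-day windows advancing by 5 days, each
  multiplied by an independent lognormal factor (σ = `segment_scale_jitter`,
  emulating per-request resampling — this is what makes stitching
  non-trivial), scaled to max = 100, rounded to integers.

Defaults: baseline 100, amplitude 50 (peak-to-trough equal to the mean —
a strongly rhythmic term), acrophase 03:00 local (a night-peaking,
insomnia-like term), noise SD 5 (5% of baseline), weekend gain 1.2,
jitter σ 0.15, 15 days per side. The jitter magnitude is a plausibility
choice — the real per-request resampling noise is not published.

Seven-day windows at a five-day stride tile spans of 7+5k days, so a
30-day span leaves a 3-day tail outside any complete window. The
convenience generator therefore pads the simulated span *after* the
analysis window to the next alignment (15+15 → 32 days, 6 windows) so the
post window is fully covered; the low-level segmenter drops incomplete
tails with a warning.

What the generator does **not** emulate: individual-user heterogeneity
and chronotype distributions, multi-region mixtures, non-stationary trend
or seasonality in the baseline, autocorrelated noise, and Google's actual
(unpublished) sampling mechanism. Passing recovery tests therefore show
the pipeline is correct under its own assumptions — not that real search
data satisfy them.

## Numerical choices

* Circular means raise an error when the mean resultant length is below
  1e-9 (no mean direction exists).
* Results of `x mod 24` that round to exactly 24.0 are mapped to 0 so
  phases always lie in [0, 24).
* The vector circular mean minimizes squared *chordal* distance; the
  exhaustive squared-*arc*-distance minimizer used as a test oracle
  agrees with it only for concentrated samples (within 0.001 h for
  within-sample SD ≤ 0.3 h, diverging by a few thousandths of an hour
  beyond that). Daily phase samples in this analysis are far tighter.
* RNG streams: dataset generation spawns independent child seeds for
  intensity noise and window jitter from the single user seed
  (deterministic, bit-reproducible).

## Problem sizes

Validation runs use 30–32-day simulated transitions, 1,000 flat days for
F-test calibration, 20 replicates per social-coupling level for the
end-to-end recovery curve, and 500 replicates for the year-ANOVA null
calibration — sizes at which every Monte-Carlo band used in the tests is
comfortably resolved.

## Known limitations

* The stand-in rhythm model is a single 24-h harmonic; strongly
  non-sinusoidal daily shapes (sharp evening spikes) bias the fitted
  acrophase toward the waveform's centre of mass.
* The equal-variance t-test and ANOVA treat daily phases as independent;
  day-to-day autocorrelation in real search behaviour would make the
  reported p-values anti-conservative.
* Only the Italian CET/CEST rule is implemented; live data retrieval and
  reproduction of the published table from fresh downloads are out of
  scope (the published numbers are carried as packaged reference data).
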