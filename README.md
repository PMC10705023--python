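# rsvphase

Diurnal phase analysis of Google-Trends-style relative search volume (RSV)
around Daylight Saving Time (DST) transitions.

When the civil clock jumps by ±60 minutes, any behaviour driven purely by
*social time* (the clock on the wall) should shift its daily rhythm by the
full hour in UTC, while a behaviour anchored to *solar time* or the
endogenous circadian clock should not move at all. Hourly search-volume
time series let this be measured population-wide: the clock time at which
searches for a term peak (its **acrophase**) can be compared across the 15
days before and after a transition. Shifts between 0 and 60 minutes
indicate partial circadian (rather than purely social) control of search
timing. This package is for chronobiologists and infodemiologists who want
that analysis as tested, reusable code.

## The model

Google Trends delivers hourly RSV in 7-day windows, each independently
rescaled to max = 100. The pipeline is:

1. **Stitching.** Consecutive windows share two calendar days; the ratio of
   the shared days' sums gives a normalization coefficient
   `c_k = Σ(ref overlap) / Σ(incoming overlap)` that chains every window
   back onto the first week's scale.
2. **Per-day cosinor.** Each calendar UTC day (24 points) is fitted with a
   single-harmonic cosinor

   ```
   y_t = M + A·cos(2π(t − φ)/24) + e_t
   ```

   via the linear form `y_t = M + β₁cos(ωt) + β₂sin(ωt)`, giving mesor `M`,
   amplitude `A = √(β₁²+β₂²)` and acrophase `φ = atan2(β₂,β₁)/ω mod 24`.
   The zero-amplitude F test on (2, 21) df gives the fit p-value; days with
   p > 0.05 are dropped. The Rhythmicity Index `RI = r·2A` multiplies the
   Pearson correlation between fit and data by the fitted oscillation range.
3. **Circular phase comparison.** Daily acrophases are averaged with the
   vector circular mean, outliers removed by the Tukey boxplot rule
   (1.5×IQR fences, applied after unwrapping about the circular mean so
   midnight-straddling clusters are not split), and the pre/post sides
   compared with a two-tailed unpaired Student t-test. The signed shift is
   reported in minutes in (−720, 720]: negative = advance, positive = delay.
4. **Year trend.** A one-way year-effect ANOVA plus a least-squares drift
   slope (minutes/year) test whether phases move across years.

A synthetic generator reproduces the observation model — civil-clock
anchored cosine intensity (CET/CEST), configurable **social coupling
fraction** of the 60-min shift, weekend level modulation, event spikes,
Gaussian noise, and per-window lognormal rescaling with max-100 integer
quantization — with exact per-day ground-truth acrophases for validation.

## Worked example

Simulate a fully social-clock-driven term through a spring transition and
recover the shift:

```python
from rsvphase import SimulationConfig, run_pipeline

cfg = SimulationConfig(season="spring", transition_year=2018,
                       social_fraction=1.0, term="insomnia", seed=42)
table, log = run_pipeline([cfg])
print(table[table.scope == "2018"].iloc[0])
```

which prints (abridged):

```
word               insomnia
phase_pre_hhmm        01:59
phase_post_hhmm       01:01
delta_min            -58.60
p_value                 0.0
n_pre                    15
n_post                   11
```

The underlying rhythm peaked at 03:00 local civil time (02:00 UTC under
CET); after the clocks moved forward the rhythm followed the social clock,
so its UTC acrophase advanced by the full hour — recovered here as
−58.6 min (estimation noise under per-window rescaling and integer
quantization) with a vanishing t-test p-value; four noisy post-transition
days were dropped by the outlier filter.
Setting `social_fraction=0.5` instead recovers ≈ −30 min: the signature of
a rhythm only partially driven by the social clock.

The same analysis runs from the shell:

```bash
rsvphase simulate --term insomnia --season spring --year 2018 \
    --social-fraction 0.6 --seed 42 --out data/
rsvphase analyze --input data/ --term insomnia --season spring --year 2018 \
    --out results.csv
# -> insomnia spring 2018: pre 1.99 h, post 1.43 h, delta -33.3 min, p = 3e-12
```

`rsvphase pipeline --config study.yaml --seed 5 --out out/` runs a whole
multi-word, multi-year synthetic study and writes the summary table plus a
log of days dropped at each stage.

The published phase table the analysis format mirrors (11 words × 2
seasons, mean pre/post phases and shifts of 25–60 min) ships with the
package: `rsvphase.table1()`.

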