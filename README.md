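# dcecurve

Non-parametric analysis of DCE-MRI signal-intensity–time curves for
discriminating prostate cancer from normal peripheral-zone tissue.

In dynamic contrast-enhanced MRI a region of interest is imaged repeatedly
while a contrast bolus passes through it, yielding a curve S(t) of signal
intensity against time. `dcecurve` characterises each curve by six
semiquantitative descriptors and asks a study-design question: *how short
and how coarse can the acquisition be before the descriptors stop
discriminating cancer from normal tissue?* It is aimed at researchers in
quantitative imaging and biostatistics who want a tested, reusable
implementation of this workflow — including a calibrated synthetic cohort
generator, since per-patient curve data are rarely shareable.

## The method

For a curve with onset of enhancement at time T₀, pre-contrast intensity
S₀, maximum Sₘ at time Tₚ (searched, by default, within the first minute
after onset), final intensity S_final at the end of the measurement T_max:

| descriptor | definition | units |
|---|---|---|
| onset time | T₀ | s |
| relative signal intensity (RSI) | 100 · Sₘ / S₀ | % |
| wash-in slope | (Sₘ − S₀) / (Tₚ − T₀) | intensity/s |
| peak enhancement | Sₘ | a.u. |
| wash-out | 100 · (S_final − Sₘ) / Sₘ | % |
| wash-out slope | (S_final − Sₘ) / (T_max − Tₚ) | intensity/s |

A prognostic score is the linear predictor ("sum of logits") of a logistic
regression of tissue class on the descriptors after backward Wald
elimination (drop the covariate with the largest p while p > 0.2).
Discrimination is estimated by leave-one-pair-out cross-validation: for
every (cancer specimen, normal specimen) pair the whole score development
is re-run without both involved subjects, the held-out pair is scored, and
the C-statistic is the fraction of pairs where the case scores strictly
higher. The full experiment repeats this over a grid of 16 measurement
lengths (2–13 min) × 7 temporal resolutions (1.6–30.4 s), i.e. 112
acquisition settings and 112 × 97 = 10,864 curves for the default cohort.

## Worked example

```
$ dcecurve simulate --seed 1 --out-dir demo
wrote 97 curves for 97 specimens to demo

$ dcecurve validate --curves demo/curves.tsv --metadata demo/metadata.csv \
    --resolution 8.0 --length 2.5
C-statistic: 1.0000 (2350/2350 concordant pairs, 0 failed fits); final model:
onset_time_s, rsi_pct, wash_in_slope, peak_intensity, wash_out_pct, wash_out_slope
```

The simulated cohort has 47 cancer and 50 normal specimens from 54
subjects (43 subjects contribute one of each). Extracting the descriptors
at full resolution and length and taking group medians:

```python
import dcecurve as dc
curves, records, _ = dc.generate_cohort(seed=1)
table = dc.build_feature_table(curves, records)
print(table[table.valid].groupby("tissue")[list(dc.CURVE_FEATURE_NAMES)]
      .median().round(3))
```

```
        onset_time_s  rsi_pct  wash_in_slope  peak_intensity  wash_out_pct  wash_out_slope
tissue
cancer          32.0  414.796          0.853          65.410       -42.401          -0.037
normal          33.6  331.314          0.531          42.252       -51.803          -0.029
```

The generator is calibrated so that these medians land on the reference
values for cancer vs normal peripheral-zone tissue (RSI 422% vs 330%,
wash-in slope 0.870 vs 0.539, peak 67 vs 42, wash-out slope −0.037 vs
−0.029, onset 32 s); the small deviations above are finite-sample noise at
n = 47/50. The C-statistic of 1.0 reflects a deliberately clean simulation:
the generator's spread is narrow enough to make group medians reproducible,
which also makes the groups nearly separable — see `docs/methods.md` for
why real-data C-statistics are much lower.

The full 112-setting experiment, with report files (Table-2-style C
matrix, ranked best models, machine-readable long format, config echo):

```
$ dcecurve grid --seed 1 --out-dir run/
```

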