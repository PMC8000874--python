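# cartt2 — longitudinal cartilage T2 mapping and texture analysis

`cartt2` is a quantitative-MRI analysis pipeline for studying post-traumatic
cartilage degeneration in vitro. It targets the standard drop-tower impaction
model: osteochondral samples are injured with a falling weight (energy
`E = mgh`, impact velocity `V = √(2gh)`), imaged longitudinally with a
multi-spin-echo sequence, and analysed for changes in the transverse
relaxation time T2 — a marker of collagen network integrity, organization and
water content — and in the spatial texture of the T2 map.

The package provides, as tested library code:

- **`cartt2.phantom`** — a synthetic-data generator producing longitudinal
  multi-echo stacks, ground-truth T2 maps and ROI masks for three exposure
  arms (unimpacted controls; low-impact band-like transitional-zone lesion;
  high-impact diffuse widespread lesion) over four time points, with Rician
  magnitude noise.
- **`cartt2.relaxometry`** — pixel-wise mono-exponential fitting
  `S(TE) = S0·exp(−TE/T2)` as a statsmodels-style model:
  `T2Model(series, mask, schedule).fit()` returns a `T2MapResults` with T2,
  S0, R² and fit-mask rasters and a `summary()`.
- **`cartt2.layers`** — automatic splitting of a sample ROI into equally
  thick superficial and deep layers along the sample's full width.
- **`cartt2.texture`** — masked gray-level co-occurrence matrices (one-pixel
  offset; 0°, 45°, 90°, 135°) and the features contrast, homogeneity, energy
  (angular second moment) and variance, averaged over orientations.
- **`cartt2.stats`** — the longitudinal battery: Friedman + Dunn within
  groups over time, Kruskal–Wallis (+ Dunn) between groups per time point,
  per-sample relative changes `Δx = (T2tx/T2t0 − 1)·100 %` compared by
  one-way ANOVA + Tukey HSD, all at α = 0.01.
- **`cartt2.cli`** — `cartt2 protocol|simulate|fit|layers|texture|stats`.

## Worked example

```python
from cartt2 import run_study

samples, table, results = run_study(rng_seed=1)   # 7 CONT / 14 LIMP / 14 HIMP
whole = table[(table.measure == "t2_mean") & (table.roi == "whole")]
print(whole.groupby(["group", "time_point"])["value"].mean().round(1))
print(results.friedman[("HIMP", "whole", "t2_mean")].p_value)
```

prints the group-mean whole-sample T2 trajectory (ms)

```
group  time_point
CONT   t0    33.8
       t1    34.8
       t2    36.0
       t3    35.4
HIMP   t0    35.5
       t1    40.3
       t2    44.6
       t3    54.9
LIMP   t0    31.1
       t1    34.3
       t2    38.9
       t3    39.9
```

and `4.01e-09` for the high-impact within-group Friedman test: controls
drift by a few percent over 72 h, low-impact samples rise by ~9 ms and
high-impact samples by ~19 ms, a highly significant time effect. The
`results` object also carries the Kruskal–Wallis, ANOVA/Tukey and Dunn
post-hoc outcomes plus publication-style summary tables
(`results.measure_table("t2_mean")`, `results.delta_summary("t2_mean")`).

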