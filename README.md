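# sacquant

Quantification toolkit for three assays used to measure chromosome-
segregation fidelity and spindle-assembly-checkpoint (SAC) fitness costs in
budding yeast:

- **Colony sectoring (chromosome loss).** Cells carrying a nonessential
  chromosome fragment form red or half-red colonies when they lose it.
  `sacquant` segments plate photographs (median + top-hat background
  flattening, intensity thresholding, watershed separation of touching
  colonies), classifies each colony along the L\*a\*b red–green axis, and
  reports loss events — fully red plus at-least-half-sectored colonies —
  per 1000 plated, with exact Clopper–Pearson intervals and Fisher's exact
  strain comparisons.
- **Kinetochore spot fluorescence.** Integrated 6×6-pixel spot intensities
  from z-stacks, background-corrected by the median of the surrounding
  ring (or a nearby 6×6 area), reference normalisation, and the
  unattached-kinetochore-number estimator
  `k = round(32 · f_u / (f_u + f_s))` from the fluorescence ratio of the
  unattached cluster to total kinetochore signal.
- **Growth kinetics.** Doubling times from 96-well OD600 time series:
  OLS of log10(OD) on time over a fixed OD window (the same window for
  every well of an experiment), with doubling time = log10(2)/slope.

A synthetic-data module generates plates, spot stacks and logistic growth
curves with known ground truth, so every pipeline is validated end to end
without external data. See `docs/methods.md` for the models, parameter
defaults and their rationale.

## Worked example

```python
from sacquant import (
    ColonyCounter, generate_plate, estimate_loss_rate, compare_loss_rates,
    percent_change,
)

# a synthetic plate with known ground truth, analysed blind
img, truth = generate_plate(n_colonies=250, loss_fraction=0.02, seed=11)
records, result = ColonyCounter().analyze(img)
print(f"detected {result.n_total} colonies "
      f"({result.n_half} half-sectored, {result.n_red} fully red); "
      f"ground truth: {len(truth.colonies)} colonies, {truth.n_loss} loss events")

# loss rates from colony counts (events, colonies plated)
wt = estimate_loss_rate((18, 5081))
eng = estimate_loss_rate((3, 6596))
print(f"wild type: {wt.rate_per_1000:.2f} per 1000 "
      f"(95% CI {wt.ci95[0]:.2f}-{wt.ci95[1]:.2f})")
print(f"engineered: {eng.rate_per_1000:.2f} per 1000 "
      f"(95% CI {eng.ci95[0]:.2f}-{eng.ci95[1]:.2f})")
cmp = compare_loss_rates(wt, eng)
print(f"rate ratio {cmp.ratio:.1f}, Fisher two-sided p = {cmp.p_two_sided:.2e}")
print(f"doubling-time increase: {percent_change(164, 144):.1f}%")
```

Output:

```
detected 250 colonies (2 half-sectored, 1 fully red); ground truth: 250 colonies, 3 loss events
wild type: 3.54 per 1000 (95% CI 2.10-5.59)
engineered: 0.45 per 1000 (95% CI 0.09-1.33)
rate ratio 7.8, Fisher two-sided p = 8.98e-05
doubling-time increase: 13.9%
```

All 250 synthetic colonies are found and classified correctly. A strain
with 18 loss events in 5081 colonies loses the fragment at 3.54 per 1000;
one with 3 events in 6596 at 0.45 per 1000 — an ~8-fold difference that
Fisher's exact test calls highly significant. A doubling time of 164 min
against a 144 min reference is a 13.9% (~14%) growth-rate cost.

The doubling-time estimator also composes with sklearn:

```python
from sacquant import DoublingTimeEstimator, GrowthModel, generate_growth_curve
import math

curve = generate_growth_curve(GrowthModel(doubling_time=144, capacity=math.inf,
                                          noise_sd=0.0), seed=0)
est = DoublingTimeEstimator(od_range=(0.1, 0.5)).fit(curve)
est.doubling_time_   # 144.000...
est.r_squared_       # 1.0
```

## Command line

```sh
sacquant simulate plate --n-colonies 250 --seed 1 --out-dir plates/
sacquant count-plate plates/plate_seed1.png --out counts/
sacquant loss-rate counts/plate_summary.csv
sacquant spot-quant stacks/*.tif --out spots.csv
sacquant doubling-time reads.csv --map platemap.csv --od-range 0.1:0.5
sacquant exact-test 18 5063 3 6593
```

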