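# vesica

Ultrasound-style quantification of rat bladder wall thickness (BWT) on
synthetic B-mode phantoms: the area-based thickness estimator, ellipsoid
volume estimation, the filling-dependence law and its plateau, the
baseline-normalised filling-corrected BWT ratio, and the radiation
dose–response group analysis.

## The problem

Radiation cystitis — inflammatory bladder injury after pelvic
radiotherapy — can be followed non-invasively in rodent models by
measuring bladder wall thickening on high-frequency ultrasound. Two
methodological obstacles stand in the way of a reliable readout:

1. **Operator dependence.** A caliper placed at one spot of the wall is
   not reproducible. Instead, the mean wall thickness is defined through
   the wall *area* (BWA) over a fixed 4-mm segment of the central sagittal
   scan: `BWT_mean = BWA / 4 mm`.
2. **Filling dependence.** The wall thins as the bladder fills,
   empirically as `t(V) = c·V^(−1/3)` (thickness ∝ 1/radius for a
   near-spherical organ), flattening into a plateau of ≈ 0.30 mm above
   ≈ 1.5 mL. Longitudinal comparisons therefore use the corrected,
   baseline-normalised ratio

   `ratio(t) = [BWT(t)·2R(t)] / [BWT(t0)·2R(t0)]`,

   with `2R = 2√(A/π)` the mean diameter from the lumen area. Because
   `t ∝ 1/R`, the product `BWT·2R` is filling-invariant, so an untreated
   bladder has ratio 1 at any filling.

This package implements that entire analysis as a tested library plus CLI,
exercised on synthetic data with exact ground truth: rendered B-mode-like
phantoms (anechoic lumen, hyperechoic wall, Rayleigh speckle, optional
air-bubble shadow and near-field echo artifacts) and simulated longitudinal
cohorts — a control group (n = 6) and two irradiated groups (n = 9 each,
25–30 Gy and 35–40 Gy) with log-normal thickening effects moment-matched
to calibrated group statistics. It is aimed at preclinical imaging
methodologists who want to validate or extend the measurement chain before
applying it to real scans.

## Worked example

```python
import numpy as np
from vesica import (ThicknessLaw, fit_power_law, plateau_onset,
                    min_detectable_effect, EffectDesign)
from vesica.cohort import generate_filling_series

law = ThicknessLaw()          # calibrated: mean over 1.5-3.0 mL = 0.30 mm
print("coefficient c =", round(law.coefficient, 4), "mm*mL^(1/3)")
print("t(2.0 mL) =", round(law.ventral_thickness(2.0), 4), "mm")

series = generate_filling_series(law, n_rats=4,
                                 volumes_per_rat=np.linspace(0.2, 3.0, 10),
                                 noise_cv=0.05, seed=0)
ventral = series[series["side"] == "ventral"]
fit = fit_power_law(ventral["volume_mL"], ventral["t_meas_mm"])
print(f"fitted exponent p = {fit.exponent:.3f} (generating: -1/3)")
res = plateau_onset(fit, (0.2, 3.0), tolerance=0.15)
print(f"plateau onset = {res.onset_ml:.2f} mL, plateau mean = {res.plateau_mean_mm:.3f} mm")
print("minimum detectable effect at n=9:",
      round(min_detectable_effect(9, EffectDesign()), 2))
```

prints

```
coefficient c = 0.3898 mm*mL^(1/3)
t(2.0 mL) = 0.3093 mm
fitted exponent p = -0.333 (generating: -1/3)
plateau onset = 1.41 mL, plateau mean = 0.305 mm
minimum detectable effect at n=9: 1.32
```

The coefficient is the thickness at 1 mL; the fitted exponent recovers the
generating −1/3 from a noisy 40-point series; the detected plateau (where
the fitted curve stays within 15% of its interval mean) starts at 1.41 mL
with mean 0.305 mm; and two groups of nine are sensitive to a standardised
effect of 1.3 at α = 0.05, power 0.80.

The full pipeline — generate a cohort, render one phantom per rat and
scan day, measure on pixels, correct for filling, summarise — runs from
the shell:

```sh
vesica run-all --seed 0 --out out/
```

which writes `cohort.csv`, `manifest.csv`, phantom PNGs + JSON sidecars,
`measurements.csv`, `ratios.csv`, `table1.csv`/`table1.json`,
`filling_fit.json`, and prints the group report, e.g. (seed 0):

```
35-40Gy
  day  4: mean±SD 1.50±0.33  median (min–max) 1.50 (1.12–2.20)  events 5/9
  day 28: mean±SD 1.54±0.45  median (min–max) 1.52 (0.80–2.10)  events 6/9
control
  day  4: mean±SD 1.08±0.07  median (min–max) 1.08 (0.99–1.16)
  day 28: mean±SD 0.89±0.09  median (min–max) 0.87 (0.76–0.99)
  35-40Gy vs control (day 28): U=49.0, p=0.007592 [exact enumeration]
  ...
```

Each row is one group at one follow-up day: the corrected BWT ratio's
mean ± SD, median (min–max), and — for irradiated groups — the number of
rats exceeding both the control maximum and the effect size 1.3. At these
small n a single seed scatters around the calibrated group means; the
recovery tests average 200 rats per group. `vesica simulate`,
`vesica analyze --manifest ... --mode auto|oracle` and
`vesica filling-series` run the stages separately.

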