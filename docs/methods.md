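# Methods

`vesica` simulates and analyses a non-invasive ultrasound protocol for
quantifying bladder wall thickening in rats, of the kind used to follow
acute radiation cystitis after single-fraction irradiation. Everything is
synthetic: the package generates the data it analyses, with exact ground
truth, so every estimator can be validated end to end.

## The measurement model

**Wall thickness.** The mean bladder wall thickness of one B-mode sagittal
scan is defined as an area, not a caliper distance:

    BWT_mean = BWA / L,      L = 4 mm,

where BWA is the wall-band area integrated over a segment of length L
centered on the mid-sagittal axis. Averaging over a fixed segment rather
than a single operator-chosen position is what makes the readout
reproducible. On pixel masks the area is a pixel count times `spacing**2`;
polygon delineations use the shoelace area after clipping to the segment
window. No sub-pixel boundary refinement is attempted; the error budget is
two pixels (0.04 mm at the default 0.02 mm/px).

One geometric consequence of the definition is worth stating: on a strongly
curved wall (small bladder, thick wall) the vertical chord through the band
slightly exceeds the normal thickness, so BWT_mean carries a small positive
bias that grows with t/R (about +1% at plateau fillings, +5% at the extreme
0.2 mL / 0.9 mm corner). This is a property of the area-over-segment
method itself, not of the segmentation; the test suite checks the
measurement against the analytic area-based expectation everywhere and
against the normal thickness in the thin-wall regime.

**Volume.** Bladder volume from a 3D scan uses the ellipsoid approximation
`V = (4/3)*pi*a*b*c` with a, b, c the *semi*-axes in mm (divided by 1000
for mL). Caliper-style full-axis inputs are supported explicitly via
`EllipsoidAxes.from_caliper`, which halves them — applying the formula to
full axes would overestimate the volume eightfold.

**Mean diameter.** The lumen cross-section area A of the central sagittal
scan yields the circle-equivalent mean diameter `2R = 2*sqrt(A/pi)`. This
is the simplest area-to-diameter map and makes the filling correction exact
for spherical geometry.

## The filling law and its plateau

The ventral wall thins with filling as `t(V) = c * V**p` with `p = -1/3`
(thickness inversely proportional to lumen radius for a near-spherical
organ). The default coefficient is calibrated so that the *interval mean*
of the law over 1.5–3.0 mL equals 0.30 mm, giving `c ≈ 0.3898 mm*mL^(1/3)`.
With this exponent the curve deviates from its plateau mean by at most
13.5% across 1.5–3.0 mL, consistent with a reported bound of about 15%; the
upper filling bound of 3.0 mL matters here, since larger bladders would
stretch that bound.

The dorsal wall reads thinner (gravity compresses it in supine imaging):
`t_d = t_v * (1 - delta(V))` with the deficit decaying linearly from
`delta0 = 0.20` at 0.2 mL to zero at 3.0 mL, so the ventral–dorsal gap
shrinks with distension.

**Fitting.** `fit_power_law` is ordinary least squares of log t on log V —
the natural estimator under multiplicative measurement noise, closed-form,
and exact on noiseless power-law data.

**Plateau detection.** "Almost constant above some filling" is made
operational as: the smallest grid volume V\* (grid step 0.01 mL) such that
the *fitted* curve stays within a relative tolerance (default 0.15) of its
closed-form interval mean over [V\*, Vmax]. On the calibrated law this
yields V\* ≈ 1.41 mL at tolerance 0.15 and exactly 1.5 mL at the law's own
maximum deviation of 13.5%. A curve too steep to settle returns a "no
plateau" result rather than raising. Note the estimated onset inherits the
variance of the fitted exponent: under the default noisy filling series
(4 rats × 10 fillings, CV 5%) its standard error is about 0.04 mL.

## The filling-corrected, baseline-normalised ratio

Longitudinal thickening is quantified as

    ratio(t) = [BWT(t) * 2R(t)] / [BWT(t0) * 2R(t0)],

i.e. each thickness is rescaled to a common reference volume via the
concurrent mean diameter before normalising to baseline; the reference
radius cancels algebraically, so none is configurable. Because the filling
law says `t ∝ 1/R`, the product `BWT * 2R` is filling-invariant: an
unirradiated spherical bladder has ratio exactly 1 no matter how full it is
at either scan. This self-consistency between the filling law and the
correction is asserted analytically (exact) and through the pixel pipeline
(within 3%, the quantisation budget).

Ratios are computed from ventral measurements only — the dorsal side is
systematically biased and is the one compromised by both modelled
artifacts. Scans acquired below the plateau onset are *flagged*
(`below_plateau_flag`), not excluded: the correction extrapolates outside
its validated regime there, but dropping such animals would bias a
dose–response analysis against exactly the bladders most damaged by
radiation.

## The synthetic cohort generator

The generator *is* the study design: a control group (n = 6) and two
irradiated groups (n = 9, single fractions of 25–30 Gy and 35–40 Gy),
scanned at baseline (day −1) and on days 4 and 28 after irradiation.

* **Effect multipliers.** Radiation-induced thickening is a per-rat,
  per-day multiplier M on the filling law (`t_v = M * c * V**(-1/3)`),
  drawn from a log-normal distribution moment-matched (closed-form moment
  inversion, exact to machine precision) to the calibrated group
  statistics: control 0.94 ± 0.13 (day 4) and 0.94 ± 0.10 (day 28);
  25–30 Gy 1.32 ± 0.41 and 1.30 ± 0.21; 35–40 Gy 1.47 ± 0.29 and
  1.90 ± 0.83. A log-normal is used because ratios are positive and the
  calibrated medians sit well below the maxima (right skew); no
  mechanistic radiobiology (no LQ model, no repair kinetics) is implied.
  The control mean of 0.94 is reproduced by calibration, not modelled.
* **Fillings.** Imaging sessions draw V uniform on 1.8–2.8 mL (the
  "fully filled" protocol keeps scans inside the plateau). An option
  (`n_impaired_high_dose`) gives a chosen number of high-dose rats a
  low-capacity filling (0.8–1.4 mL) at the last follow-up, emulating
  radiation-impaired reservoirs; it is off by default.
* **Measurement noise.** The bookkeeping (non-pixel) route applies
  multiplicative Gaussian noise per scan: CV 0.08 on thickness and CV 0.01
  on the area-derived diameter (areas average over many boundary pixels,
  so their diameter is far more precise than a thickness read off ~15
  pixels). Propagated to the baseline-normalised ratio this gives an SD of
  ≈ 0.08·√2 ≈ 0.113 for an effect-free animal, consistent with the
  calibrated control SDs of 0.10–0.13. The pixel route realises
  measurement noise physically, through speckle.
* **Seeding.** One root seed; every draw comes from a
  `SeedSequence(seed, spawn_key=(stream, group, rat, timepoint))`
  substream, so enlarging a group leaves existing animals' draws
  untouched, and cohort, bookkeeping-noise and speckle streams are
  mutually independent.

## The phantom renderer

Phantoms are flat-intensity tissue models, not wave-propagation
simulations: lumen 0.05, wall 0.80, background tissue 0.35 (arbitrary
units), multiplied by a unit-mean Rayleigh speckle field with ~1 px
Gaussian grain, clipped to [0, 1]. The transducer is at the top, so row 0
is ventral. The wall band is the set of pixels within Euclidean distance
t(side) of the lumen ellipse (exact for the default circular lumen, EDT
for general ellipses). Default grid 1024×1024 at 0.02 mm/px (20.5 mm
field): a full bladder at 2.8 mL is 17.5 mm across and must fit with wall
margins, which a 512-px grid at this spacing cannot accommodate; the
pipeline grows the grid further in 128-px steps for rare extreme
geometries. Images are saved as 8-bit PNG with a JSON ground-truth
sidecar (half-a-grey-level quantisation is negligible against the
delineation thresholds).

Two artifacts can be injected, both compromising only the dorsal side: an
air-bubble shadow (anechoic cone from the stated point, opening downward;
real shadow geometry is not well quantified, so the default 8° half-angle
is a free parameter) and a near-field echo (bright band over
the top `depth_mm`, default 1 mm, which stays above the ventral wall of a
plateau-filled bladder). Injection updates the sidecar so measurements can
flag the dorsal side as compromised.

## Automated delineation

Delineation is specified only for phantoms from this renderer (known
intensity classes); it is not a general bladder segmenter.

1. Smooth with a Gaussian (default σ = 1.5 px).
2. Lumen: largest connected component below the lumen/tissue midpoint
   (0.20), hole-filled; at least 1 mm², else a `MeasurementError` naming
   the failure.
3. Wall, per column of the 4-mm window centered on the lumen centroid:
   scan outward from the lumen edge; the inner boundary is the crossing of
   the lumen/wall midpoint (0.425), the outer boundary the first drop
   below the wall/tissue midpoint (0.575) after the wall core. Midpoint
   thresholds make both edges unbiased under symmetric blur; per-column
   integer rounding averages out across the ~200 columns.

On noiseless renders this recovers the ground-truth masks pixel for pixel;
under default speckle the measured thickness stays within 2 px of truth.
The lumen threshold (0.20, below the lumen/wall midpoint to reject
background tissue) biases the lumen radius inward by ~1.5 px, i.e. area
−0.8%, diameter −0.4% — which cancels in the baseline-normalised ratio.
Columns that fail to yield a wall run are skipped; more than 10% failures
set a `low_confidence` flag (an air-bubble shadow typically destroys the
dorsal run entirely).

## Group statistics

Descriptives use the sample SD (n−1); a single observation reports SD 0
with a `degenerate` flag. A *thickening event* requires a rat's ratio to
strictly exceed both the control group's same-day maximum and the design
effect size 1.3 (strictness and the conjunction are this package's
conventions; monotonicity in each ratio is property-tested). Group
contrasts use the two-sided Mann–Whitney–Wilcoxon test: the exact null
distribution when `n1*n2 <= 100` and the pooled sample is tie-free (9 vs 9
and 9 vs 6 are exact), otherwise the normal approximation with continuity
and tie corrections. No multiple-testing correction is applied across the
three pairwise comparisons by default; `holm=True` enables a Holm
step-down adjustment. The design arithmetic uses the standard two-sample
normal-approximation identity `d = (z_{1-α/2} + z_{1-β})·sqrt(2/n)`, which
gives 1.32 (i.e. 1.3 at one decimal) at n = 9, α = 0.05 two-sided,
power 0.80.

## Problem sizes and numerical choices

* Acceptance-style recoveries run 50 phantoms for the plateau mean and 200
  rats per group (two scans each) for the dose-response means; at ~0.2 s
  per rendered-and-measured scan a full recovery is a few minutes on one
  CPU.
* Plateau grid step 0.01 mL; interval means of fitted curves are closed
  form (power-function integral), with the log branch at p = −1.
* Degenerate inputs raise `ValueError` (configs, non-positive volumes,
  empty samples) or `MeasurementError` (unmeasurable scans); per-animal
  measurement failures inside the pipeline become flagged rows, not
  aborts, mirroring a study that retains compromised bladders.

## What passing tests do and do not show

The phantoms share the renderer's own intensity model, so delineation
accuracy here says nothing about segmenting real preclinical B-mode images
(acoustic shadowing, depth-dependent gain, tissue heterogeneity and probe
PSF are all absent). The cohort generator reproduces group-level means and
SDs by construction; recovery tests therefore validate the *measurement
and correction chain*, not the biology. Within those limits the tests show
that the area-over-segment estimator, the 1/∛V correction and the
rank-sum group analysis recover the generating truth without material bias
at the study's sample sizes.
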