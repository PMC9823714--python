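# Methods

## The measurement model

A seed lot is excited with narrow-band blue light (λ_e ≈ 450 nm) and the
photoluminescence of the seed surfaces is collected over a detection band.
The sensed quantity is the band-integrated flux

    Phi = ∫[λ1, λ2] φ_l(λ) dλ

with φ_l(λ) the emission spectrum treated as an intensity density per nm.
Spectra are represented as sampled curves (strictly increasing wavelengths,
nonnegative intensities), which makes the piecewise-linear interpolant the
natural continuous model; the trapezoidal rule on the native grid is then
*exact* for that model, so no higher-order quadrature is used. Band limits
are clipped to the sampled support and contribute zero outside it — a
conservative choice that never extrapolates an instrument's range.

Two bands appear in practice: 480–620 nm, the emission support seen on a
laboratory spectrofluorimeter, and 490–650 nm, the detection band of the
portable device (its lower edge backed off the excitation source, its upper
edge set by the photodiode). The package default is the device band
490–650 nm; both are ordinary parameters.

Fluxes carry their unit (`relative_units` or `lumens`) and band, and the unit
is enforced at every interface: predictions and device signals only accept
lumens, conversions refuse to run twice. The default conversion factor
6.25e-9 lm/r.u. is derived from the packaged calibration table, whose lm and
r.u. columns are proportional to within ~0.2 % across all nine rows; it is a
config value, not a constant of nature, and should be recalibrated per
instrument against a reference source.

## Calibration

Germination B (%) is regressed on flux by ordinary least squares,

    B = a · (Phi · 1e6) + b ,

with the slope stored explicitly in % per microlumen to keep the 1e6
convention out of call sites. R² is the squared Pearson correlation, which
for simple OLS equals explained over total sum of squares. The packaged
registry carries the published three-point calibrations per species at their
printed precision; refitting the packaged table reproduces them to one unit
in the last printed digit (the galega slope computes to 5.615 against a
quoted 5.62 — consistent with the quoted value having been rounded from
slightly different unrounded fluxes; the package reports its own computed
fit and does not adjust toward the quoted digit).

Predictions are clamped to [0, 100] % with a `clamped` flag, and fluxes
outside the training range set an `extrapolated` flag rather than failing:
the device's purpose is to read new lots, so extrapolation is a warning
condition, not an error. No confidence intervals are computed — the
calibrations are three-point fits and interval estimates would be
decorative.

## The decision loop

Repeated readings of one lot are averaged arithmetically (they share unit
and band by construction). The verdict rule is:

- **sow** when predicted germination ≥ threshold (inclusive — a lot exactly
  at the required germination is sufficient);
- **rescarify** when below threshold with scarification cycles remaining;
- **reject** when below threshold and the cycle budget is spent. The reject
  branch is this package's addition: repeated scarification destroys an
  increasing fraction of seeds, so a lot that cannot reach the threshold in
  `max_cycles` passes needs manual handling, not an infinite loop.

Defaults: `max_cycles = 2` (in production one pass is usual, two at most —
more is uneconomical) and `threshold_pct = 70`, which is **agronomically
arbitrary**: no published threshold exists, and deployments must set it per
crop and market. Thresholds above 100 % are accepted by the library and are
simply unreachable (predictions are clamped), which gives a clean way to
exercise the reject path.

`run_cycle_simulation` models re-scarification as a constant per-cycle flux
multiplier. Lot-level data show double scarification raising flux 1.66× for
galega, 3.0× for clover and 3.9× for alfalfa, so multipliers in the 1.3–2×
per-cycle range are realistic; the mechanism is a deliberate simplification
(real gains decay with each pass as intact coat area shrinks).

## LED scoring

The effective output of a candidate source against the seeds' sensitivity is

    k_ee = Phi_eff / Phi_full = ∫ φ_LED(λ) S(λ) dλ / ∫ φ_LED(λ) dλ .

S(λ) is taken to be the luminescence excitation spectrum normalised to unit
peak — the sensing-relevant meaning of "seed sensitivity", since source
photons matter exactly in proportion to how efficiently they excite
luminescence. Curves passed with a different normalisation are rescaled with
a warning. Both integrals are evaluated on the union of the two curves'
grids restricted to the LED's support (both integrands vanish outside it),
so neither sampling biases the product; the score is scale-invariant in the
LED spectrum, dimensionless, and clipped to [0, 1] against floating-point
undershoot. Note that for smooth spectra k_ee < 1 even for a source centred
exactly on the sensitivity peak — only a sensitivity that is 1 across the
whole source support gives 1.

The same functional doubles as the band-overlap diagnostic: scoring the
source spectrum against the *receiver's* sensitivity gives the fraction of
source light the detector would see directly; above a configurable
threshold the device needs time gating (the hardware design uses a 0.75 ms
delay between flash and measurement, kept here as a descriptive config
constant) or a cut-off filter.

A step-edged (rectangular) sensitivity is representable only up to the grid
resolution: the piecewise-linear model turns the step into a ramp across one
sample gap. Tests that compare against step-function oracles therefore give
rectangles explicit 1e-6 nm edge ramps.

## Synthetic data

The generator emulates the *published constraints* on the real spectra, not
their unpublished shapes:

- **Emission**: a single Gaussian mode at the species peak (galega 536 nm,
  clover 516 nm, alfalfa 517 nm) truncated to the 480–620 nm support, with
  σ = 25 nm chosen so the mode fills that support plausibly. The amplitude
  is scaled so the trapezoidal integral over the support equals the
  requested flux exactly before noise, making generated curves usable as
  flux fixtures with known ground truth.
- **Excitation / sensitivity**: Gaussian peaks at the published centres
  (galega a 462/485 nm doublet, clover 448 nm, alfalfa 450 nm), peak
  heights 1.0/0.9 for the doublet and σ = 9 nm — narrow enough that the
  doublet resolves into two modes as the measured spectra show. Height
  ratio and widths are shape choices; only peak positions and supports are
  data.
- **Seed lots**: the calibration line is inverted, Phi = (B − b)/a µlm, and
  readings are drawn as Phi·(1 + ε) with ε ~ N(0, σ). Noise is
  multiplicative because luminescence intensity noise scales with signal.
  At σ = 0 the decision pipeline recovers B exactly (closed-form round
  trip); σ = 2 % with ~100 readings reflects a realistic bench session.
- **Device**: U_ph = U_0 + R·Phi (+ optional Gaussian noise), with dark
  voltage U_0 = 0.72 mV from the bench tests. Bench photovoltages imply
  responsivities that differ between species and levels (optical geometry
  and gain were evidently not held constant), so R is an explicit
  per-experiment parameter, the bench table ships as a fixture only, and
  the photovoltages are not treated as a validation target.

Every stochastic operation takes an explicit seed and is bit-reproducible;
nothing reads global RNG state.

What passing tests on synthetic data do **not** show: real emission spectra
are asymmetric and lot-heterogeneous, real noise has a shot-plus-drift
structure, and real scarification gains saturate. The synthetic layer
validates the *pipeline arithmetic* end to end, not the biology.

## Numerical choices and edge cases

- Quadrature: trapezoid on the native grid everywhere; band endpoints are
  interpolated in so adjacent bands add exactly (additivity to 1e-9
  relative is a tested invariant, as is exact homogeneity under intensity
  scaling).
- OLS is delegated to `scipy.stats.linregress`; tests check it against the
  closed-form normal equations and a brute-force grid search around the
  optimum. Degenerate designs (all fluxes equal, < 2 points) raise typed
  errors rather than returning NaN.
- Ties: the sow verdict is inclusive at the threshold; LED ranking breaks
  score ties alphabetically for stable reports.
- File formats are deliberately minimal (two-column delimited spectra,
  one-flux-per-line readings, JSON registry, TOML config) with line-numbered
  parse errors, duplicate-wavelength detection and sort-on-read.

## Problem sizes

Everything here is desk-scale: calibrations are 3-point fits, synthetic
round trips use 100 readings per lot and 200 replicates at most, and the
full test suite plus the acceptance script complete in a few seconds on one
CPU core.
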