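# seedlum

Optical quality control for seed scarification. Hard-coated forage legumes
(galega, clover, alfalfa) germinate poorly unless their seed coat is abraded
— *scarified* — before sowing, and the only classical way to check whether a
scarification pass worked is a germination trial that takes days. Seed-surface
**photoluminescence** gives an answer in seconds: scarified coats luminesce
more brightly under blue (~450 nm) excitation, and the emitted flux tracks the
lot's germination linearly. `seedlum` implements the complete computational
pipeline of such a sensor for engineers building or simulating one:

1. **Flux integration** — the photoluminescence flux is the band integral of
   the emission spectrum,

   Φ = ∫<sub>λ₁</sub><sup>λ₂</sup> φ<sub>l</sub>(λ) dλ,

   integrated with the trapezoidal rule over the detection band (default
   490–650 nm) and converted from instrument relative units to lumens by a
   reference calibration factor.
2. **Calibration** — species-specific ordinary-least-squares lines
   **B = a·(Φ·10⁶) + b**, where B is germination (%) and Φ is flux (lm),
   with R². A JSON registry ships with published calibrations for galega
   (a = 5.62, b = 22.9, R² = 0.9999), clover (1.59, 5.72, 0.9919) and
   alfalfa (3.66, 28.2, 0.9315).
3. **Decision loop** — average repeated readings, predict germination, and
   issue a verdict: *sow* (prediction ≥ threshold), *rescarify* (below
   threshold, cycles remain) or *reject* (cycle budget spent).
4. **LED scoring** — candidate excitation sources are ranked by effective
   output k<sub>e,e</sub> = Φ<sub>eff</sub>/Φ<sub>full</sub> =
   ∫φ<sub>LED</sub>S dλ / ∫φ<sub>LED</sub> dλ against the seeds' spectral
   sensitivity S(λ) (their luminescence excitation spectrum, peak-normalised),
   plus a source/receiver band-overlap diagnostic for gating/filter decisions.
5. **Synthetic data** — Gaussian-shaped emission/excitation spectra honouring
   the species' published peak positions, noisy seed-lot simulation that
   inverts the calibration lines, and a linear photodetector model above a
   0.72 mV dark voltage.

## Worked example

```python
import seedlum as sl

table = sl.reference_tables().germination_flux          # packaged measurements
points = [sl.CalibrationPoint(float(r.flux_lm), float(r.germination_pct))
          for r in table[table.species == "galega"].itertuples()]
model = sl.fit_calibration(points)
print(model.slope_pct_per_microlumen, model.intercept_pct, model.r_squared)
# 5.61484356051419 22.91571671113266 0.9998740648146417

pred = sl.predict_germination(model, sl.FluxValue(3.57e-6, sl.LUMENS))
print(round(pred.germination_pct))                       # 43
```

The fitted galega line predicts 43 % germination for a lot whose mean flux is
3.57 µlm — the value observed for double-scarified galega in the calibration
data. The `examples/` directory holds short narrative scripts for each
capability (calibration, the decision loop, LED ranking, end-to-end
simulation); each prints its numbers with a line on what they mean. A thin
CLI wraps the same functions:

```sh
seedlum predict --species galega --flux-lm 3.57e-6     # prints 43
seedlum decide --species clover --readings readings.txt --threshold 70
# exit code 0 = sow, 2 = rescarify, 3 = reject
```

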