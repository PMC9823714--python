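"""Simulate the full bench measurement for a lot of known germination.

Generates a synthetic galega emission spectrum with the tabulated
double-scarification flux (572 r.u.), integrates it, converts to lumens,
simulates 50 noisy device readings of a 43%-germination lot, and shows the
decision and the photodetector voltage the device would display.
"""

import seedlum as sl

# 1. Emission spectrum with a known band integral.
curve = sl.make_emission("galega", target_flux_ru=572.0, noise_sd=0.02, seed=7)
flux_ru = sl.integrate_flux(curve, (480, 620))
flux_lm = sl.to_lumens(flux_ru, sl.DEFAULT_RU_TO_LM)
print(f"integrated flux: {flux_ru.value:.1f} r.u. = {flux_lm.value:.3e} lm")

# 2. A lot of known 43% germination measured 50 times with 2% flux noise.
registry = sl.default_registry()
lot, true_flux = sl.make_lot(registry["galega"], 43.0, n_measurements=50,
                             noise_sd=0.02, seed=7)
result = sl.decide(lot, registry, threshold_pct=40.0, max_cycles=2)
print(f"mean of {len(lot.readings)} readings: {result.mean_flux.value:.3e} lm "
      f"(truth {true_flux:.3e} lm)")
print(f"predicted germination {result.predicted_germination_pct:.1f}% -> {result.verdict}")

# 3. What the photodetector reports (responsivity from the bench tests).
device = sl.DeviceModel(responsivity_mV_per_lm=3.92e4)
u = sl.device_signal(device, result.mean_flux)
print(f"photovoltage {u:.2f} mV (dark level {device.dark_voltage_mV} mV)")
print("\nThe noise-free flux inverts the calibration exactly; with 2% noise")
print("the 50-reading average keeps the prediction within a fraction of a percent.")
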