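"""Synthetic spectra, seed lots, and device signals for testing and simulation.

No spectral raw data ship with hard-seeded forage calibrations beyond peak
positions and working ranges, so this module generates Gaussian-shaped stand-in
spectra that honour those constraints: single-mode emission peaking at
516-536 nm on a 480-620 nm support, and one- or two-peak excitation spectra in
the 440-500 nm region.  Seed-lot simulation inverts a calibration line to find
the flux consistent with a chosen germination and adds multiplicative
measurement noise; the device model maps flux to photodetector voltage above a
dark level.  Everything stochastic is reproducible from an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .calibration import CalibrationModel
from .decision import MeasurementSession
from .exceptions import UnitMismatchError, ValidationError
from .spectra import LUMENS, RELATIVE_UNITS, FluxValue, SpectralCurve, integrate_flux

__all__ = [
    "SpeciesProfile",
    "DeviceModel",
    "SPECIES_PROFILES",
    "DARK_VOLTAGE_MV",
    "make_emission",
    "make_excitation",
    "make_lot",
    "device_signal",
    "reference_tables",
    "ReferenceTables",
]

#: Photodetector output with no light, in mV (measured device dark level).
DARK_VOLTAGE_MV = 0.72


@dataclass(frozen=True)
class SpeciesProfile:
    """Spectral shape parameters for one species.

    ``excitation_peaks_nm`` is a list of (center, relative height) pairs;
    emission is single-mode at ``emission_peak_nm`` truncated to
    ``emission_range_nm``.  Peak widths are Gaussian sigmas in nm; the true
    widths and the two-peak height ratio are not published, so these are
    shape choices that respect the printed peaks and supports.
    """

    species: str
    excitation_peaks_nm: tuple[tuple[float, float], ...]
    emission_peak_nm: float
    emission_range_nm: tuple[float, float] = (480.0, 620.0)
    peak_width_nm: float = 25.0
    # narrow enough to resolve the galega 462/485 nm doublet as two modes
    excitation_width_nm: float = 9.0

    def __post_init__(self):
        for center, height in self.excitation_peaks_nm:
            if not 380 <= center <= 700:
                raise ValidationError(f"excitation peak {center} nm outside 380-700 nm")
            if height <= 0:
                raise ValidationError("peak heights must be positive")
        if not 380 <= self.emission_peak_nm <= 700:
            raise ValidationError("emission peak outside 380-700 nm")
        if self.peak_width_nm <= 0 or self.excitation_width_nm <= 0:
            raise ValidationError("peak widths must be positive")


#: Default profiles for the three calibrated species.
SPECIES_PROFILES: dict[str, SpeciesProfile] = {
    "galega": SpeciesProfile(
        "galega", excitation_peaks_nm=((462.0, 1.0), (485.0, 0.9)), emission_peak_nm=536.0
    ),
    "clover": SpeciesProfile(
        "clover", excitation_peaks_nm=((448.0, 1.0),), emission_peak_nm=516.0
    ),
    "alfalfa": SpeciesProfile(
        "alfalfa", excitation_peaks_nm=((450.0, 1.0),), emission_peak_nm=517.0
    ),
}


@dataclass(frozen=True)
class DeviceModel:
    """Linear photodetector model: U_ph = U_0 + responsivity * Phi + noise.

    ``dark_voltage_mV`` is the no-light output U_0; ``responsivity_mV_per_lm``
    is an experiment-specific linear gain (optical geometry and amplifier
    dependent, so not a universal constant).
    """

    responsivity_mV_per_lm: float
    dark_voltage_mV: float = DARK_VOLTAGE_MV
    noise_sd_mV: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.responsivity_mV_per_lm <= 0:
            raise ValidationError("responsivity must be positive")
        if self.dark_voltage_mV < 0 or self.noise_sd_mV < 0:
            raise ValidationError("dark voltage and noise sd must be >= 0")


def _profile(species_or_profile: str | SpeciesProfile) -> SpeciesProfile:
    if isinstance(species_or_profile, SpeciesProfile):
        return species_or_profile
    try:
        return SPECIES_PROFILES[species_or_profile]
    except KeyError:
        raise ValidationError(
            f"no species profile for {species_or_profile!r}; "
            f"known: {', '.join(sorted(SPECIES_PROFILES))}"
        ) from None


def make_emission(
    species_or_profile: str | SpeciesProfile,
    target_flux_ru: float,
    grid_step_nm: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> SpectralCurve:
    """Generate a single-mode Gaussian emission spectrum with a known flux.

    The Gaussian bump sits at the profile's emission peak, truncated to the
    emission range, with its amplitude scaled so that the trapezoidal band
    integral over the full emission range equals ``target_flux_ru`` exactly
    before noise.  Multiplicative Gaussian noise (sd as a fraction of signal)
    is then applied pointwise, reproducibly for a fixed ``seed``.
    """
    profile = _profile(species_or_profile)
    if target_flux_ru <= 0:
        raise ValidationError("target flux must be positive")
    if grid_step_nm <= 0:
        raise ValidationError("grid step must be positive")
    if noise_sd < 0:
        raise ValidationError("noise sd must be >= 0")
    lo, hi = profile.emission_range_nm
    grid = np.arange(lo, hi + grid_step_nm / 2, grid_step_nm)
    shape = np.exp(-0.5 * ((grid - profile.emission_peak_nm) / profile.peak_width_nm) ** 2)
    raw = float(np.trapezoid(shape, grid))
    inten = shape * (target_flux_ru / raw)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        inten = inten * (1.0 + rng.normal(0.0, noise_sd, size=inten.size))
        inten = np.clip(inten, 0.0, None)
    return SpectralCurve(grid, inten, role="emission", label=f"{profile.species} emission (synthetic)")


def make_excitation(
    species_or_profile: str | SpeciesProfile,
    grid_step_nm: float = 1.0,
    normalize: bool = True,
) -> SpectralCurve:
    """Generate the (possibly two-peak) excitation spectrum of a species.

    Peak-normalised by default so it can serve directly as the seed
    sensitivity S(lambda) for LED scoring.
    """
    profile = _profile(species_or_profile)
    if grid_step_nm <= 0:
        raise ValidationError("grid step must be positive")
    centers = np.array([c for c, _ in profile.excitation_peaks_nm])
    lo = centers.min() - 4 * profile.excitation_width_nm
    hi = centers.max() + 4 * profile.excitation_width_nm
    grid = np.arange(lo, hi + grid_step_nm / 2, grid_step_nm)
    inten = np.zeros_like(grid)
    for center, height in profile.excitation_peaks_nm:
        inten += height * np.exp(-0.5 * ((grid - center) / profile.excitation_width_nm) ** 2)
    role = "excitation"
    if normalize:
        inten = inten / inten.max()
        role = "sensitivity"
    return SpectralCurve(grid, inten, role=role, label=f"{profile.species} excitation (synthetic)")


def make_lot(
    model: CalibrationModel,
    true_germination_pct: float,
    n_measurements: int = 10,
    noise_sd: float = 0.0,
    seed: int | None = None,
    scarification_cycles: int = 0,
) -> tuple[MeasurementSession, float]:
    """Simulate flux readings for a seed lot of known germination.

    Inverts the calibration line, flux = (B - intercept) / slope microlumens,
    and draws readings flux * (1 + eps_i) with eps_i ~ N(0, noise_sd).
    Returns the session and the noise-free flux in lumens; at noise 0 the
    decision pipeline recovers ``true_germination_pct`` exactly.
    """
    if not 0 <= true_germination_pct <= 100:
        raise ValidationError("germination must lie in [0, 100] %")
    if model.slope_pct_per_microlumen == 0:
        raise ValidationError("model slope is zero; flux is not identifiable")
    if n_measurements < 1:
        raise ValidationError("need at least one measurement")
    if noise_sd < 0:
        raise ValidationError("noise sd must be >= 0")
    flux_lm = (true_germination_pct - model.intercept_pct) / model.slope_pct_per_microlumen * 1e-6
    if flux_lm < 0:
        raise ValidationError(
            f"germination {true_germination_pct}% is below the model intercept; "
            "no nonnegative flux maps to it"
        )
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=n_measurements) if noise_sd > 0 else np.zeros(n_measurements)
    readings = tuple(
        FluxValue(max(flux_lm * (1.0 + e), 0.0), LUMENS) for e in eps
    )
    session = MeasurementSession(
        species=model.species, readings=readings, scarification_cycles=scarification_cycles
    )
    return session, flux_lm


def device_signal(model: DeviceModel, flux: FluxValue) -> float:
    """Photodetector voltage (mV) for a given flux in lumens.

    U_ph = U_0 + responsivity * Phi (+ Gaussian noise when configured); the
    net optical signal is recovered as U_ph - U_0.
    """
    if flux.unit != LUMENS:
        raise UnitMismatchError("device_signal expects a flux in lumens")
    u = model.dark_voltage_mV + model.responsivity_mV_per_lm * flux.value
    if model.noise_sd_mV > 0:
        rng = np.random.default_rng(model.seed)
        u += float(rng.normal(0.0, model.noise_sd_mV))
    return float(u)


@dataclass(frozen=True)
class ReferenceTables:
    """Published reference measurements shipped with the package.

    ``germination_flux``: per species and scarification cycle count, the
    observed germination (%) and photoluminescence flux in r.u. and lm.
    ``photovoltage``: bench-test photodetector voltages (mV) per species and
    germination level, above the dark voltage ``dark_voltage_mV``.
    """

    germination_flux: pd.DataFrame
    photovoltage: pd.DataFrame
    dark_voltage_mV: float = DARK_VOLTAGE_MV


def reference_tables() -> ReferenceTables:
    """Load the packaged reference measurement tables."""
    root = resources.files("seedlum.data")
    with resources.as_file(root.joinpath("germination_flux.csv")) as path:
        gf = pd.read_csv(path)
    with resources.as_file(root.joinpath("photovoltage.csv")) as path:
        pv = pd.read_csv(path)
    return ReferenceTables(germination_flux=gf, photovoltage=pv)
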