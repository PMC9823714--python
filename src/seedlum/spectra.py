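"""Spectral curves, band-integrated photoluminescence flux, and spectral file I/O.

The core quantity of the sensing method is the photoluminescence flux

    Phi = integral over [lambda1, lambda2] of phi_l(lambda) dlambda

where ``phi_l`` is the emission spectrum of the seed surface (intensity per nm)
and the band is the working spectral range of the detector.  Fluxes are carried
in instrument-native relative units (r.u.) and converted to lumens by a single
reference calibration factor.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Sequence

import numpy as np

from .exceptions import SpectrumFormatError, UnitMismatchError, ValidationError

__all__ = [
    "ROLES",
    "RELATIVE_UNITS",
    "LUMENS",
    "SpectralCurve",
    "FluxValue",
    "integrate_flux",
    "to_lumens",
    "to_relative",
    "resample",
    "read_spectrum",
    "write_spectrum",
]

#: Recognised roles of a spectral curve.
ROLES = ("emission", "excitation", "led", "sensitivity")

RELATIVE_UNITS = "relative_units"
LUMENS = "lumens"


@dataclass(frozen=True)
class SpectralCurve:
    """A sampled spectrum: strictly increasing wavelengths (nm) and
    nonnegative intensities (relative units per nm).

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths in nanometres, length >= 2.
    intensities
        Nonnegative intensities, same length as ``wavelengths_nm``.
    role
        One of :data:`ROLES`; ``sensitivity`` curves are expected to be
        normalised to unit peak.
    label
        Free-text identifier (species, LED part number, ...).
    """

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    role: str = "emission"
    label: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities", inten)
        if wl.ndim != 1 or inten.ndim != 1:
            raise ValidationError("wavelengths and intensities must be 1-D")
        if wl.size != inten.size:
            raise ValidationError(
                f"length mismatch: {wl.size} wavelengths vs {inten.size} intensities"
            )
        if wl.size < 2:
            raise ValidationError("a spectral curve needs at least 2 samples")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(inten)):
            raise ValidationError("non-finite values in spectral curve")
        if np.any(np.diff(wl) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if np.any(inten < 0):
            raise ValidationError("intensities must be nonnegative")
        if self.role not in ROLES:
            raise ValidationError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.role == "sensitivity" and inten.max() > 1 + 1e-9:
            raise ValidationError(
                "sensitivity curves must be normalised to peak <= 1 "
                f"(max intensity {inten.max():g})"
            )

    @property
    def support(self) -> tuple[float, float]:
        """The sampled wavelength range (min, max) in nm."""
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def scaled(self, factor: float) -> "SpectralCurve":
        """Return a copy with intensities multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValidationError("scale factor must be positive")
        return replace(self, intensities=self.intensities * factor)

    def peak_normalized(self, role: str | None = None) -> "SpectralCurve":
        """Return a copy scaled to unit peak intensity (role optionally changed)."""
        peak = float(self.intensities.max())
        if peak <= 0:
            raise ValidationError("cannot normalise an all-zero spectrum")
        return SpectralCurve(
            self.wavelengths_nm,
            self.intensities / peak,
            role=role or self.role,
            label=self.label,
        )


@dataclass(frozen=True)
class FluxValue:
    """A band-integrated flux with its unit and integration band.

    ``unit`` is ``"relative_units"`` or ``"lumens"``; ``band`` records the
    (lambda1, lambda2) interval in nm the value was integrated over.
    """

    value: float
    unit: str = RELATIVE_UNITS
    band: tuple[float, float] | None = None

    def __post_init__(self):
        if self.unit not in (RELATIVE_UNITS, LUMENS):
            raise ValidationError(f"unit must be {RELATIVE_UNITS!r} or {LUMENS!r}")
        if not np.isfinite(self.value) or self.value < 0:
            raise ValidationError(f"flux value must be finite and >= 0, got {self.value}")
        if self.band is not None:
            lo, hi = self.band
            if not lo < hi:
                raise ValidationError(f"band must satisfy lambda1 < lambda2, got {self.band}")
            object.__setattr__(self, "band", (float(lo), float(hi)))


def _check_band(band: Sequence[float]) -> tuple[float, float]:
    lo, hi = float(band[0]), float(band[1])
    if not lo < hi:
        raise ValidationError(f"band must satisfy lambda1 < lambda2, got ({lo}, {hi})")
    return lo, hi


def integrate_flux(curve: SpectralCurve, band: Sequence[float]) -> FluxValue:
    """Band-integrate a spectrum with the trapezoidal rule.

    The integral of intensity over ``band`` = (lambda1, lambda2), clipped to
    the curve's sampled range (no extrapolation: wavelengths outside the
    samples contribute zero).  Exact for the piecewise-linear spectrum the
    sampled representation implies.  Result unit is relative units.

    Raises
    ------
    ValidationError
        If the band is inverted or does not overlap the sampled range.
    """
    lo, hi = _check_band(band)
    if curve.role != "emission":
        warnings.warn(
            f"integrating a {curve.role!r}-role curve as an emission flux",
            stacklevel=2,
        )
    s_lo, s_hi = curve.support
    if hi <= s_lo or lo >= s_hi:
        raise ValidationError(
            f"band ({lo}, {hi}) nm does not overlap sampled range ({s_lo}, {s_hi}) nm"
        )
    a, b = max(lo, s_lo), min(hi, s_hi)
    wl, inten = curve.wavelengths_nm, curve.intensities
    inside = (wl > a) & (wl < b)
    xs = np.concatenate(([a], wl[inside], [b]))
    ys = np.concatenate(
        ([np.interp(a, wl, inten)], inten[inside], [np.interp(b, wl, inten)])
    )
    value = float(np.trapezoid(ys, xs))
    return FluxValue(max(value, 0.0), RELATIVE_UNITS, (lo, hi))


def to_lumens(flux: FluxValue, factor_lm_per_ru: float) -> FluxValue:
    """Convert a relative-units flux to lumens via the reference calibration factor."""
    if factor_lm_per_ru <= 0:
        raise ValidationError("conversion factor must be positive")
    if flux.unit != RELATIVE_UNITS:
        raise UnitMismatchError(
            "flux is already in lumens; refusing a second conversion"
        )
    return FluxValue(flux.value * factor_lm_per_ru, LUMENS, flux.band)


def to_relative(flux: FluxValue, factor_lm_per_ru: float) -> FluxValue:
    """Inverse of :func:`to_lumens`."""
    if factor_lm_per_ru <= 0:
        raise ValidationError("conversion factor must be positive")
    if flux.unit != LUMENS:
        raise UnitMismatchError("flux is not in lumens")
    return FluxValue(flux.value / factor_lm_per_ru, RELATIVE_UNITS, flux.band)


def resample(curve: SpectralCurve, grid: Sequence[float]) -> SpectralCurve:
    """Linearly interpolate a curve onto ``grid``; zero outside the sampled range."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValidationError("grid must be a strictly increasing sequence of >= 2 wavelengths")
    inten = np.interp(grid, curve.wavelengths_nm, curve.intensities, left=0.0, right=0.0)
    return SpectralCurve(grid, inten, role=curve.role, label=curve.label)


# ---------------------------------------------------------------------------
# File I/O: two-column delimited text, '#' comments, column 1 = nm, column 2
# = intensity.  Comma or whitespace separated.


def _parse_rows(lines: Iterable[str]) -> list[tuple[int, float, float]]:
    rows: list[tuple[int, float, float]] = []
    for lineno, raw in enumerate(lines, start=1):
        text = raw.split("#", 1)[0].strip()
        if not text:
            continue
        parts = text.replace(",", " ").split()
        if len(parts) != 2:
            raise SpectrumFormatError(
                f"expected 2 columns (wavelength, intensity), got {len(parts)}: {text!r}",
                line=lineno,
            )
        try:
            wl, inten = float(parts[0]), float(parts[1])
        except ValueError:
            raise SpectrumFormatError(f"non-numeric cell in {text!r}", line=lineno) from None
        rows.append((lineno, wl, inten))
    return rows


def read_spectrum(source: str | IO[str], role: str = "emission", label: str = "") -> SpectralCurve:
    """Read a two-column spectral text file (or stream) into a :class:`SpectralCurve`.

    Rows are sorted by wavelength on read (a warning is emitted when the file
    was unsorted); duplicate wavelengths and non-numeric cells raise
    :class:`~seedlum.exceptions.SpectrumFormatError` with the line number.
    """
    if hasattr(source, "read"):
        rows = _parse_rows(source)
        name = getattr(source, "name", "<stream>")
    else:
        with open(source, "r", encoding="utf-8") as fh:
            rows = _parse_rows(fh)
        name = str(source)
    if len(rows) < 2:
        raise SpectrumFormatError(f"{name}: need at least 2 data rows, got {len(rows)}")
    wls = np.array([r[1] for r in rows])
    uniq, counts = np.unique(wls, return_counts=True)
    if np.any(counts > 1):
        dup = uniq[counts > 1][0]
        lineno = next(r[0] for r in rows if r[1] == dup)
        raise SpectrumFormatError(f"duplicate wavelength {dup:g} nm", line=lineno)
    if np.any(np.diff(wls) < 0):
        warnings.warn(f"{name}: rows were not sorted by wavelength; sorting", stacklevel=2)
        rows = sorted(rows, key=lambda r: r[1])
    return SpectralCurve(
        [r[1] for r in rows], [r[2] for r in rows], role=role, label=label or name
    )


def write_spectrum(curve: SpectralCurve, dest: str | IO[str]) -> None:
    """Write a curve as two-column comma-separated text (with a comment header)."""
    header = f"# seedlum spectrum role={curve.role}"
    if curve.label:
        header += f" label={curve.label}"
    body = "\n".join(
        f"{wl:.10g},{inten:.10g}"
        for wl, inten in zip(curve.wavelengths_nm, curve.intensities)
    )
    text = header + "\n" + body + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(text)
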