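"""Effective-output scoring of excitation light sources.

A candidate LED is scored against the spectral sensitivity of the seeds
(their luminescence excitation spectrum, peak-normalised) by the
effective-output ratio

    k_ee = Phi_eff / Phi_full
         = integral(phi_LED(lambda) * S(lambda)) / integral(phi_LED(lambda))

i.e. the fraction of the source's output that the seeds can actually use.
The same ratio doubles as a source/receiver band-overlap diagnostic: when an
excitation source leaks into the detector's sensitive band, gating or
cut-off filtering is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .exceptions import ValidationError
from .spectra import SpectralCurve, resample

__all__ = [
    "LEDCandidate",
    "effective_output",
    "rank_leds",
    "band_overlap",
]


@dataclass(frozen=True)
class LEDCandidate:
    """A named candidate light source; ``score`` is filled by :func:`rank_leds`."""

    name: str
    spectrum: SpectralCurve
    score: float | None = None

    def __post_init__(self):
        if self.score is not None and not 0 <= self.score <= 1:
            raise ValidationError("score must lie in [0, 1]")


def _as_sensitivity(curve: SpectralCurve) -> SpectralCurve:
    """Peak-normalise a curve for use as S(lambda), warning when rescaling."""
    peak = float(curve.intensities.max())
    if peak <= 0:
        raise ValidationError("sensitivity curve is identically zero")
    if abs(peak - 1.0) > 1e-9:
        warnings.warn(
            f"sensitivity curve peak is {peak:g}; normalising to unit peak",
            stacklevel=3,
        )
        return curve.peak_normalized(role="sensitivity")
    if curve.role != "sensitivity":
        return replace(curve, role="sensitivity")
    return curve


def effective_output(led: SpectralCurve, sensitivity: SpectralCurve) -> float:
    """The effective-output ratio k_ee in [0, 1].

    Both integrals are evaluated with the trapezoidal rule on the union of
    the two curves' wavelength grids (restricted to the LED's support, where
    both integrands live), so neither sampling biases the product.
    """
    sens = _as_sensitivity(sensitivity)
    lo, hi = led.support
    grid = np.union1d(led.wavelengths_nm, sens.wavelengths_nm)
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size < 2:
        grid = led.wavelengths_nm
    led_i = resample(led, grid).intensities
    sens_i = resample(sens, grid).intensities
    full = float(np.trapezoid(led_i, grid))
    if full <= 0:
        raise ValidationError("LED spectrum has zero integral; cannot score")
    eff = float(np.trapezoid(led_i * sens_i, grid))
    return min(max(eff / full, 0.0), 1.0)


def rank_leds(
    candidates: Sequence[LEDCandidate], sensitivity: SpectralCurve
) -> list[LEDCandidate]:
    """Score every candidate and sort by score descending (ties by name).

    A candidate whose spectrum cannot be scored aborts the ranking with an
    error naming it, rather than being silently dropped.
    """
    if not candidates:
        raise ValidationError("need at least one LED candidate")
    scored = []
    for cand in candidates:
        try:
            score = effective_output(cand.spectrum, sensitivity)
        except ValidationError as exc:
            raise ValidationError(f"candidate {cand.name!r}: {exc}") from exc
        scored.append(replace(cand, score=score))
    return sorted(scored, key=lambda c: (-c.score, c.name))


def band_overlap(
    source: SpectralCurve,
    receiver: SpectralCurve,
    threshold_fraction: float = 0.01,
) -> tuple[float, bool]:
    """Fraction of the source's output falling in the receiver's sensitive band.

    Returns ``(overlap, gating_needed)`` where ``gating_needed`` is True when
    the overlap exceeds ``threshold_fraction`` — i.e. the excitation source
    shines into the detector's band and time gating or a cut-off filter is
    required.
    """
    if not 0 <= threshold_fraction <= 1:
        raise ValidationError("threshold fraction must lie in [0, 1]")
    overlap = effective_output(source, receiver.peak_normalized(role="sensitivity"))
    return overlap, overlap > threshold_fraction
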