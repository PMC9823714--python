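"""Linear germination-flux calibration models.

The sensor predicts seed germination B (%) from the band-integrated
photoluminescence flux Phi (lm) of the seed surface through a species-specific
ordinary-least-squares line

    B = a * (Phi * 1e6) + b

with the slope ``a`` expressed in % per microlumen so that the 1e6 scaling of
the conventional notation is explicit.  A small JSON registry maps species
labels to fitted models; the package ships a default registry with published
calibrations for galega, clover and alfalfa.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib import resources
from typing import IO, Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import DegenerateDataError, UnitMismatchError, UnknownSpeciesError, ValidationError
from .spectra import LUMENS, FluxValue

__all__ = [
    "CalibrationPoint",
    "CalibrationModel",
    "Prediction",
    "fit_calibration",
    "predict_germination",
    "flux_ratio",
    "load_registry",
    "save_registry",
    "default_registry",
    "lookup",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One (flux, germination) calibration observation for a seed lot."""

    flux_lm: float
    germination_pct: float
    scarification_cycles: int = 0
    species: str = ""

    def __post_init__(self):
        if self.flux_lm < 0:
            raise ValidationError("flux must be >= 0")
        if not 0 <= self.germination_pct <= 100:
            raise ValidationError("germination must lie in [0, 100] %")
        if self.scarification_cycles < 0:
            raise ValidationError("scarification cycle count must be >= 0")


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted line B = slope * (Phi * 1e6) + intercept with its R^2.

    ``slope_pct_per_microlumen`` is germination % per 1e-6 lm of flux;
    ``flux_range_lm`` records the training flux range so predictions outside
    it can be flagged as extrapolation.
    """

    species: str
    slope_pct_per_microlumen: float
    intercept_pct: float
    r_squared: float
    n_points: int
    flux_range_lm: tuple[float, float]
    provenance: str = ""

    def __post_init__(self):
        if not 0 <= self.r_squared <= 1:
            raise ValidationError("R^2 must lie in [0, 1]")
        if self.n_points < 2:
            raise ValidationError("a calibration needs >= 2 points")
        lo, hi = self.flux_range_lm
        if lo > hi:
            raise ValidationError("flux range min must be <= max")
        object.__setattr__(self, "flux_range_lm", (float(lo), float(hi)))


@dataclass(frozen=True)
class Prediction:
    """A germination prediction with clamping/extrapolation audit flags."""

    germination_pct: float
    clamped: bool
    extrapolated: bool


def fit_calibration(points: Sequence[CalibrationPoint]) -> CalibrationModel:
    """Ordinary least squares of germination (%) on flux (microlumens).

    R^2 is the squared Pearson correlation of flux and germination, which for
    a simple OLS line equals explained over total sum of squares.

    Raises
    ------
    DegenerateDataError
        Fewer than 2 points, or all training fluxes identical.
    """
    if len(points) < 2:
        raise DegenerateDataError(f"need >= 2 calibration points, got {len(points)}")
    flux_ulm = np.array([p.flux_lm for p in points]) * 1e6
    germ = np.array([p.germination_pct for p in points])
    if np.ptp(flux_ulm) == 0:
        raise DegenerateDataError("all calibration fluxes identical; slope is undefined")
    res = stats.linregress(flux_ulm, germ)
    # two points on an exact line: rvalue may suffer rounding; R^2 in [0, 1]
    r2 = min(max(res.rvalue**2, 0.0), 1.0)
    species = points[0].species or ""
    return CalibrationModel(
        species=species,
        slope_pct_per_microlumen=float(res.slope),
        intercept_pct=float(res.intercept),
        r_squared=float(r2),
        n_points=len(points),
        flux_range_lm=(float(flux_ulm.min() * 1e-6), float(flux_ulm.max() * 1e-6)),
        provenance=f"OLS fit of {len(points)} points",
    )


def predict_germination(model: CalibrationModel, flux: FluxValue | float) -> Prediction:
    """Predict germination (%) from a flux in lumens.

    Accepts a :class:`~seedlum.spectra.FluxValue` in lumens (relative-units
    fluxes must be converted with :func:`seedlum.spectra.to_lumens` first) or
    a bare float taken to be lumens.  The raw line value is clamped to
    [0, 100] with ``clamped`` set when clamping occurred; ``extrapolated``
    flags fluxes outside the model's training range.
    """
    if isinstance(flux, FluxValue):
        if flux.unit != LUMENS:
            raise UnitMismatchError(
                "predict_germination needs a flux in lumens; convert with spectra.to_lumens"
            )
        flux_lm = flux.value
    else:
        flux_lm = float(flux)
    if flux_lm < 0:
        raise ValidationError("flux must be >= 0")
    raw = model.slope_pct_per_microlumen * flux_lm * 1e6 + model.intercept_pct
    clamped = not 0 <= raw <= 100
    lo, hi = model.flux_range_lm
    return Prediction(
        germination_pct=float(min(max(raw, 0.0), 100.0)),
        clamped=clamped,
        extrapolated=not lo <= flux_lm <= hi,
    )


def flux_ratio(after: FluxValue, before: FluxValue) -> float:
    """Ratio of post- to pre-scarification flux (both in the same unit)."""
    if after.unit != before.unit:
        raise UnitMismatchError(
            f"cannot form a ratio of {after.unit} and {before.unit} fluxes"
        )
    if before.value <= 0:
        raise ValidationError("reference (pre-scarification) flux must be positive")
    return after.value / before.value


# ---------------------------------------------------------------------------
# Registry serialization


def _model_to_dict(model: CalibrationModel) -> dict:
    d = asdict(model)
    d.pop("species")
    d["flux_range_lm"] = list(model.flux_range_lm)
    return d


def save_registry(models: Mapping[str, CalibrationModel], dest: str | IO[str]) -> None:
    """Write a species -> model mapping as JSON."""
    payload = {sp: _model_to_dict(m) for sp, m in models.items()}
    if hasattr(dest, "write"):
        json.dump(payload, dest, indent=2)
    else:
        with open(dest, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def _registry_from_payload(payload: dict) -> dict[str, CalibrationModel]:
    registry = {}
    for species, fields in payload.items():
        registry[species] = CalibrationModel(
            species=species,
            slope_pct_per_microlumen=fields["slope_pct_per_microlumen"],
            intercept_pct=fields["intercept_pct"],
            r_squared=fields["r_squared"],
            n_points=fields["n_points"],
            flux_range_lm=tuple(fields["flux_range_lm"]),
            provenance=fields.get("provenance", ""),
        )
    return registry


def load_registry(source: str | IO[str]) -> dict[str, CalibrationModel]:
    """Load a JSON registry into a species -> :class:`CalibrationModel` mapping."""
    if hasattr(source, "read"):
        payload = json.load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
    return _registry_from_payload(payload)


def default_registry() -> dict[str, CalibrationModel]:
    """The packaged registry: published galega, clover and alfalfa calibrations."""
    text = resources.files("seedlum.data").joinpath("registry.json").read_text("utf-8")
    return _registry_from_payload(json.loads(text))


def lookup(registry: Mapping[str, CalibrationModel], species: str) -> CalibrationModel:
    """Fetch a species model, raising a helpful error listing known species."""
    try:
        return registry[species]
    except KeyError:
        raise UnknownSpeciesError(species, list(registry)) from None
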