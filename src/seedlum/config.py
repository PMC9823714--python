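"""Run configuration: detection band, unit conversion, decision thresholds.

Defaults mirror a device profile for forage-seed scarification control:
excitation near 450 nm, detection band 490-650 nm, measurement gated 0.75 ms
after the excitation flash (a documented device constant; no computation here
uses it).  The germination threshold has no published value — 70 % is an
agronomically arbitrary default that deployments must set per crop and market.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field

from .exceptions import ValidationError

__all__ = ["RunConfig", "load_config", "DEFAULT_BAND_NM", "SPECTRO_BAND_NM", "DEFAULT_RU_TO_LM"]

#: Device-mode detection band (nm).
DEFAULT_BAND_NM = (490.0, 650.0)
#: Spectrofluorimeter-style emission band (nm), matching the emission support.
SPECTRO_BAND_NM = (480.0, 620.0)
#: Relative units -> lumens conversion, derived from the published
#: calibration table (lm column / r.u. column, constant to ~0.2%).
DEFAULT_RU_TO_LM = 6.25e-9


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline settings; unknown config-file keys are rejected."""

    band_nm: tuple[float, float] = DEFAULT_BAND_NM
    ru_to_lm: float = DEFAULT_RU_TO_LM
    threshold_pct: float = 70.0
    max_cycles: int = 2
    registry_path: str | None = None
    log_level: str = "INFO"
    seed: int | None = None
    gate_delay_ms: float = 0.75  # descriptive device constant, not used in computation

    def __post_init__(self):
        lo, hi = self.band_nm
        if not lo < hi:
            raise ValidationError(f"band must satisfy lambda1 < lambda2, got {self.band_nm}")
        object.__setattr__(self, "band_nm", (float(lo), float(hi)))
        if self.ru_to_lm <= 0:
            raise ValidationError("ru_to_lm factor must be positive")
        if not 0 <= self.threshold_pct <= 100:
            raise ValidationError("germination threshold must lie in [0, 100] %")
        if self.max_cycles < 1:
            raise ValidationError("max_cycles must be >= 1")
        if self.gate_delay_ms < 0:
            raise ValidationError("gate delay must be >= 0")


_KEY_MAP = {
    ("flux", "band_nm"): "band_nm",
    ("flux", "ru_to_lm"): "ru_to_lm",
    ("decision", "threshold_pct"): "threshold_pct",
    ("decision", "max_cycles"): "max_cycles",
    ("decision", "registry_path"): "registry_path",
    ("device", "gate_delay_ms"): "gate_delay_ms",
    ("run", "log_level"): "log_level",
    ("run", "seed"): "seed",
}


def load_config(path: str, **overrides) -> RunConfig:
    """Load a TOML config file; keyword arguments override file values.

    Recognised keys::

        [flux]      band_nm = [490, 650]   ru_to_lm = 6.25e-9
        [decision]  threshold_pct = 70     max_cycles = 2   registry_path = "..."
        [device]    gate_delay_ms = 0.75
        [run]       log_level = "INFO"     seed = 7

    Unknown sections or keys raise :class:`~seedlum.exceptions.ValidationError`.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    kwargs: dict = {}
    for section, entries in raw.items():
        if not isinstance(entries, dict):
            raise ValidationError(f"top-level key {section!r} is not a section")
        for key, value in entries.items():
            target = _KEY_MAP.get((section, key))
            if target is None:
                raise ValidationError(f"unknown config key [{section}] {key}")
            if target == "band_nm":
                value = tuple(value)
            kwargs[target] = value
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**kwargs)
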