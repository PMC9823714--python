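"""Exception hierarchy shared across seedlum modules."""


class SeedlumError(Exception):
    """Base class for all seedlum domain errors."""


class ValidationError(SeedlumError, ValueError):
    """An input violates a documented precondition or invariant."""


class UnitMismatchError(SeedlumError, ValueError):
    """Flux values in incompatible units were combined or misused."""


class SpectrumFormatError(SeedlumError, ValueError):
    """A spectral text file could not be parsed.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnknownSpeciesError(SeedlumError, KeyError):
    """A species label is absent from a calibration registry."""

    def __init__(self, species: str, known: list[str]):
        self.species = species
        self.known = sorted(known)
        super().__init__(
            f"unknown species {species!r}; registry knows: {', '.join(self.known)}"
        )

    def __str__(self) -> str:  # KeyError would repr() the message
        return self.args[0]


class DegenerateDataError(SeedlumError, ValueError):
    """A fit cannot be performed (e.g. all calibration fluxes identical)."""
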