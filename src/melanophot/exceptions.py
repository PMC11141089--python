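"""Exception hierarchy for melanophot."""


class MelanophotError(Exception):
    """Base class for all package errors."""


class SpectrumFormatError(MelanophotError):
    """A spectrum file could not be parsed (bad columns, non-monotone grid)."""


class ValidationError(MelanophotError, ValueError):
    """An input violates a documented precondition (negative power, bad grid)."""


class UnitError(MelanophotError):
    """A quantity carried the wrong unit tag for the requested operation."""


class GamutError(MelanophotError):
    """A solved primary drive falls outside the device's [0, 1] range."""

    def __init__(self, message: str, primary: str | None = None):
        super().__init__(message)
        self.primary = primary


class DegenerateSystemError(MelanophotError):
    """The receptor/primary system is singular or has zero variance."""


class InsufficientDataError(MelanophotError):
    """Too few samples to compute the requested statistic."""
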