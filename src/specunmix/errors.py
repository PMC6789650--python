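"""Exception hierarchy for specunmix.

All errors raised deliberately by this package derive from
:class:`SpecUnmixError`, so callers (and the CLI) can distinguish
data/usage problems from genuine bugs.
"""


class SpecUnmixError(Exception):
    """Base class for all specunmix errors."""


class GridMismatchError(SpecUnmixError):
    """Two spectra do not share an identical wavelength grid."""


class NoIsosbesticError(SpecUnmixError):
    """No isosbestic crossing found in the searched wavelength range."""


class AmbiguousIsosbesticError(SpecUnmixError):
    """More than one candidate isosbestic crossing was found.

    Carries the candidate wavelengths so a caller can narrow the
    search range or supply the wavelength explicitly.
    """

    def __init__(self, candidates):
        self.candidates = list(candidates)
        super().__init__(
            "multiple isosbestic candidates found: "
            + ", ".join(f"{c:.2f} nm" for c in self.candidates)
            + "; narrow the search range or supply the wavelength explicitly"
        )


class InsufficientSignalError(SpecUnmixError):
    """Absorbance at the normalization wavelength is too low to divide by."""


class ConstraintError(SpecUnmixError):
    """A molar-fraction vector violates the box bounds or the sum-to-one constraint."""


class NormalizationError(SpecUnmixError):
    """A spectrum expected to be isosbestic-normalized is not."""


class UnderdeterminedError(SpecUnmixError):
    """Fewer fitted wavelengths than mixture components."""


class EmptyWindowError(SpecUnmixError):
    """A wavelength window does not intersect the spectrum grid."""


class UndefinedStatisticError(SpecUnmixError):
    """A statistic is undefined for the given data (e.g. zero total variance)."""


class DesignError(SpecUnmixError):
    """An assay design is internally inconsistent."""


class CapacityError(DesignError):
    """A design requires more wells than the plate provides."""


class LayoutError(SpecUnmixError):
    """A plate layout is invalid or inconsistent with the plate data."""


class PlateFormatError(SpecUnmixError):
    """A plate CSV does not conform to the canonical format."""


class ConfigError(SpecUnmixError):
    """An assay configuration file is invalid."""


class InsufficientDataError(SpecUnmixError):
    """Too few data points for the requested estimate."""
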