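"""Exception hierarchy shared across the package."""


class PolywhorlError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PolywhorlError):
    """A table or config file does not conform to the expected schema."""


class IntegrityError(PolywhorlError):
    """Input data violate a uniqueness or consistency constraint."""


class UndefinedStatisticError(PolywhorlError):
    """A statistic is mathematically undefined for the given sample
    (e.g. circular mean at zero resultant length, Pearson r at zero
    variance)."""


class ClassificationError(PolywhorlError):
    """Periodicity classification is impossible (e.g. every lag has an
    undefined correlation)."""


class GeometryError(PolywhorlError):
    """Lattice geometry too small or otherwise invalid for the requested
    operation."""


class NumericalInstabilityError(PolywhorlError):
    """The explicit Euler scheme produced a non-finite field, or the time
    step violates the stability bound."""


class CalibrationError(PolywhorlError):
    """Parameter search failed to find a set meeting the symmetry targets.

    Carries the best candidate found, so a failed search is still
    inspectable."""

    def __init__(self, message, best_candidate=None, report=None):
        super().__init__(message)
        self.best_candidate = best_candidate
        self.report = report
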