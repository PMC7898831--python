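"""Exception hierarchy for eqshift.

All eqshift errors derive from :class:`EqshiftError` so callers can catch
package failures with a single except clause; the subclasses distinguish
bad inputs from physically infeasible requests and from measurements that
contradict the assumed reaction system.
"""


class EqshiftError(Exception):
    """Base class for all eqshift errors."""


class InvalidInputError(EqshiftError, ValueError):
    """An argument violates a precondition (wrong sign, range, or shape)."""


class InfeasibilityError(EqshiftError):
    """The requested quantity has no physically admissible solution."""


class InconsistentMeasurementError(EqshiftError):
    """A measured conversion contradicts the assumed reaction system
    beyond the allowed tolerance (e.g. implies negative hydrolysis)."""


class FormatError(EqshiftError, ValueError):
    """A data file does not match the expected CSV layout."""


class ConditioningError(EqshiftError):
    """Reference spectra are too collinear for a reliable unmixing."""


class UndefinedConversionError(EqshiftError):
    """Both component weights are (near) zero; conversion is undefined."""


class DegenerateFitError(EqshiftError):
    """The decay fit is unidentifiable from the supplied observations."""
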