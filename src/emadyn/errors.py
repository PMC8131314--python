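"""Exception hierarchy.

Every error the library raises derives from :class:`EmadynError`, so callers
(and the CLI) can catch one base class and still report a named error.
"""


class EmadynError(Exception):
    """Base class for all emadyn errors."""


class InvalidDesignError(EmadynError):
    """A study design violates a structural rule (window, interval, items)."""


class CapViolationError(InvalidDesignError):
    """A question-set cap was exceeded (13 fixed / <=3 complaints / <=5 personal / <=26 total)."""


class ParameterError(EmadynError):
    """A simulation or model parameter is outside its admissible range."""


class CorruptRecordsError(EmadynError):
    """EMA records are inconsistent with the prompt schedule."""


class UnknownVariableError(EmadynError):
    """A requested variable is not part of the study design."""


class InsufficientDataError(EmadynError):
    """Too few observations for the requested operation; the message names the threshold."""


class CollinearityError(EmadynError):
    """Predictors are numerically collinear (condition number above the guard)."""


class InadequateDataError(EmadynError):
    """Dataset fails the measurement-adequacy rule and no override was given."""


class ExportError(EmadynError):
    """Report export failed (unwritable path, unknown format token)."""
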