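"""Exception hierarchy for daycast.

All package-raised errors derive from :class:`DaycastError` so callers can
catch the whole family with one clause while still distinguishing I/O
format problems from numerical/statistical failures.
"""


class DaycastError(Exception):
    """Base class for all daycast errors."""


class FormatError(DaycastError):
    """A file does not conform to the expected layout (missing column,
    bad cell value, unparseable date)."""


class ValidationError(DaycastError):
    """Data violates an internal consistency rule (duplicate keys,
    unresolved references, out-of-range values)."""


class DomainError(DaycastError):
    """A numeric argument lies outside its mathematical domain."""


class UnderdeterminedError(DaycastError):
    """Too few observations to fit the requested model (e.g. a cubic
    needs at least four distinct abscissae)."""


class DegenerateSystemError(DaycastError):
    """The two curves coincide; the intersection problem has no isolated
    solution."""


class FitError(DaycastError):
    """A model fit failed numerically (singular system, empty training
    set, all markers filtered out)."""
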