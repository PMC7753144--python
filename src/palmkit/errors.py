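"""Exception hierarchy.

All palmkit errors derive from :class:`PalmKitError` so callers can catch the
package's failures with one clause.  The CLI maps usage-type errors
(parameter/format/parse) to exit code 1 and data-content errors to exit code 2.
"""


class PalmKitError(Exception):
    """Base class for all palmkit errors."""


class FormatError(PalmKitError):
    """A file does not have the structure the chosen dialect requires."""


class ParseError(PalmKitError):
    """A cell or field could not be converted to the expected type."""


class ParameterError(PalmKitError, ValueError):
    """An argument is outside its admissible range."""


class DomainError(PalmKitError, ValueError):
    """A quantity was requested outside the domain of the model."""


class DataError(PalmKitError):
    """The data are structurally valid but insufficient for the operation."""


class ComparisonError(PalmKitError):
    """Two results are not comparable (e.g. different frame times)."""
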