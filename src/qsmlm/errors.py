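"""Exception types raised across the package.

All inherit from :class:`QSMLMError`, itself a ``ValueError``, so callers may
catch either the specific class or the package-wide base.
"""


class QSMLMError(ValueError):
    """Base class for all package errors."""


class FormatError(QSMLMError):
    """A localization file is structurally invalid (e.g. missing column)."""


class ParseError(QSMLMError):
    """A cell in a localization file could not be parsed as a number."""


class PlacementError(QSMLMError):
    """The requested number of qualifying ROIs could not be placed."""


class ScenarioError(QSMLMError):
    """Unknown simulation scenario name."""


class FitError(QSMLMError):
    """A fit result was used in a way that requires convergence."""
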