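"""Exception and warning hierarchy for the package.

Errors are split into two families so the CLI can map them onto stable
exit codes: :class:`InputError` (malformed tables, bad grids, unknown
formats → exit 2) and :class:`DomainError` (mathematically inadmissible
values such as a non-positive length → exit 3).
"""

from __future__ import annotations


class AadaptError(Exception):
    """Base class for all package-specific errors."""


class DomainError(AadaptError, ValueError):
    """A quantity is outside the mathematical domain of the model.

    The message names the offending field so callers can report it.
    """


class InputError(AadaptError, ValueError):
    """Malformed or inconsistent user input (files, grids, config)."""


class InsufficientDataError(InputError):
    """Too few records for the requested statistic (e.g. n < 3 for r)."""


class PlausibilityWarning(UserWarning):
    """A measurement is valid but outside the observed human range."""
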