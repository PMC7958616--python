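"""Exception taxonomy shared across the package.

Validation-type failures (bad files, bad values, out-of-range requests,
misuse of an API) derive from :class:`WabError` and map to CLI exit code 2;
runtime failures (optimizer non-convergence, I/O) map to exit code 1.
"""

from __future__ import annotations


class WabError(Exception):
    """Base class for all package-specific errors."""


class FormatError(WabError):
    """A file could not be parsed in the requested dialect."""


class DataError(WabError):
    """Parsed data violate an invariant (duplicate grid points, empty band...)."""


class RangeError(WabError):
    """A requested region or value lies outside the available data span."""


class UsageError(WabError):
    """An operation was called with arguments that make no sense together."""


class FitError(WabError):
    """The optimizer failed to converge.

    Carries a ``diagnostics`` dict (status, message, iterations, final cost)
    so callers can log or re-raise with context.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
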