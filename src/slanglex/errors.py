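"""Exception hierarchy shared across the pipeline."""

from __future__ import annotations


class SlanglexError(Exception):
    """Base class for all package errors."""


class FormatError(SlanglexError):
    """An input file does not match the expected tabular/text layout."""


class PreconditionError(SlanglexError):
    """An operation was called with arguments violating its contract."""


class DataError(SlanglexError):
    """Inputs are structurally valid but inconsistent (e.g. missing labels)."""


class ConfigurationError(SlanglexError):
    """A pipeline configuration is invalid or incomplete."""


class TransientBackendError(SlanglexError):
    """A retryable backend failure (timeouts, 5xx); retried per policy."""


class QuotaExhaustedError(SlanglexError):
    """A completion or search backend ran out of quota.

    Carries optional state (``cache``, ``partial``) so callers can
    checkpoint and resume the run once quota is restored.
    """

    def __init__(self, message: str = "backend quota exhausted", *, cache=None, partial=None):
        super().__init__(message)
        self.cache = cache
        self.partial = partial
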