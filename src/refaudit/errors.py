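"""Exception hierarchy shared across the package.

Error *values* (e.g. UNMATCHED markers, UNREGISTERED taxa) live next to the
functions that return them; everything raised lives here.
"""

from __future__ import annotations


class RefAuditError(Exception):
    """Base class for all package errors."""


class InvalidNameError(RefAuditError):
    """Organism/taxon name cannot be serialized into a query statement."""


class SourceUnavailableError(RefAuditError):
    """A record source failed (network/file), after retries.

    Deliberately distinct from a zero count: callers must never conflate
    "no sequences found" with "the search failed".
    """


class PartialFetchError(RefAuditError):
    """Some fetch batches failed; carries the partial result."""

    def __init__(self, message: str, partial: list, failures: list[str]):
        super().__init__(message)
        self.partial = partial
        self.failures = failures


class MalformedSnapshotError(RefAuditError):
    """Snapshot file unreadable; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class MalformedCSVError(RefAuditError):
    """Query CSV violates the template; carries row numbers in the message."""


class EmptyInputError(RefAuditError):
    """An operation that must produce output received zero records."""


class InvalidPlanError(RefAuditError):
    """A synthetic CoveragePlan violates its own invariants."""


class CapabilityError(RefAuditError):
    """A source was asked for an operation it does not support."""
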