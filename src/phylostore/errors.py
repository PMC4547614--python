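"""Exception hierarchy for phylostore."""

from __future__ import annotations


class PhylostoreError(Exception):
    """Base class for all phylostore errors."""


class UnsupportedVersionError(PhylostoreError):
    """Raised when a document declares an unknown NexSON syntax version."""

    def __init__(self, value: object):
        self.value = value
        super().__init__(f"unsupported NexSON syntax version: {value!r}")


class ParseError(PhylostoreError):
    """Malformed input text (XML or JSON). Carries line/column when known."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        if line is not None:
            message = f"{message} (line {line}, column {column})"
        super().__init__(message)


class InvalidDocumentError(PhylostoreError):
    """An operation that requires a valid document was given an invalid one."""

    def __init__(self, report):
        self.report = report
        codes = ", ".join(sorted({e.code.value for e in report.errors}))
        super().__init__(f"document failed validation: {codes}")


class ConversionError(PhylostoreError):
    """A document cannot be represented in the requested syntax version."""


class UnknownTargetError(PhylostoreError):
    """A tree operation referenced a node/edge that is not in the tree."""


class NotFoundError(PhylostoreError):
    """A study id does not exist in the document store."""


class SizeLimitError(PhylostoreError):
    """Serialized document exceeds the configured per-file size limit."""

    def __init__(self, size: int, limit: int):
        self.size = size
        self.limit = limit
        super().__init__(f"document is {size} bytes; limit is {limit} bytes")


class StoreError(PhylostoreError):
    """Generic storage failure (bad config, git failure, unknown parent SHA)."""


class UnknownTaxonError(PhylostoreError):
    """A taxon id is absent from the supplied taxonomy."""


class CorruptionError(PhylostoreError):
    """A requested fixture corruption cannot be applied to the document."""
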