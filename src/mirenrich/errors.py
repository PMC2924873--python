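"""Exception hierarchy shared across the package.

The split drives CLI exit codes: :class:`UsageFault` maps to exit 1,
the data-level errors map to exit 2.
"""


class MirEnrichError(Exception):
    """Base class for all errors raised by this package."""


class UsageFault(MirEnrichError):
    """The command or call was used incorrectly (exit code 1 in the CLI)."""


class InvalidIdentifierError(MirEnrichError):
    """A miRNA identifier is empty or unparseable."""


class FormatError(MirEnrichError):
    """An input file violates its declared format (exit code 2 in the CLI)."""


class ValidationError(MirEnrichError):
    """An in-memory object violates a domain invariant (exit code 2)."""


class AnalysisError(MirEnrichError):
    """The analysis cannot proceed, e.g. no input miRNA matched the
    background population (exit code 2)."""
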