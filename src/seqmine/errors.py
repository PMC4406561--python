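"""Exception hierarchy shared across the pipeline.

Every error raised on bad user input derives from :class:`SeqmineError`
so the CLI can map them to a data-error exit code.
"""


class SeqmineError(Exception):
    """Base class for all seqmine errors."""


class FormatError(SeqmineError):
    """A file violates its format (malformed line, wrong column count)."""


class ValidationError(SeqmineError):
    """Well-formed input with semantically invalid content."""


class SchemaError(SeqmineError):
    """A table is missing required columns."""


class EmptyInputError(SeqmineError):
    """An operation received no records to work on."""


class EmptyAnnotationError(SeqmineError):
    """No usable features were parsed from an annotation file."""


class DegenerateInputError(SeqmineError):
    """Input is formally valid but degenerate (zero library size, ...)."""


class GroupingError(SeqmineError):
    """A replicate grouping is inconsistent with the data."""


class ConfigurationError(SeqmineError):
    """Pipeline configuration is invalid."""


class NoTFError(SeqmineError):
    """No transcription factors among the differentially expressed genes."""


class DegenerateStratumError(SeqmineError):
    """A CMH stratum is too small to contribute a variance term."""
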