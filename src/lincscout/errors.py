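"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ValidationError/ParseError -> 2,
MissingInputError -> 3.
"""


class PipelineError(Exception):
    """Base class for all lincscout errors."""


class ParseError(PipelineError):
    """A file could not be parsed under the declared dialect."""


class ValidationError(PipelineError):
    """Parsed content violates a domain invariant."""


class MissingInputError(PipelineError):
    """A required input file or record is absent."""


class InvalidControlError(PipelineError):
    """MRA template control (P-c) band absent; no orientation call possible."""


class UndefinedNormalizationError(PipelineError):
    """All-zero expression profile cannot be normalized to its maximum."""
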