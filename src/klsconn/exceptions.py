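"""Exception hierarchy shared across the pipeline stages."""


class KlsconnError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(KlsconnError, ValueError):
    """A specification or input table failed its invariants.

    The message names the offending field or column.
    """


class DegenerateInputError(KlsconnError, ValueError):
    """Input is structurally valid but statistically degenerate
    (constant samples, zero IQR, zero-variance region, ...)."""


class GridMismatchError(KlsconnError, ValueError):
    """Two density estimates were not evaluated on the same grid."""


class ParseError(KlsconnError, ValueError):
    """A TSV/JSON artifact on disk is malformed."""


class StageError(KlsconnError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
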