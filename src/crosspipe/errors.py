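"""Exception hierarchy.

Validation errors (bad inputs) are kept distinct from format errors (unparseable
files) and computation errors so the CLI can map them to distinct exit codes.
"""


class CrossPipeError(Exception):
    """Base class for all package errors."""


class ValidationError(CrossPipeError):
    """Input violates a documented invariant (negative counts, empty groups, ...)."""


class FormatError(CrossPipeError):
    """A file could not be parsed (malformed GMT line, duplicate sample ids, ...)."""


class ComputationError(CrossPipeError):
    """A numerical stage failed (degenerate design, no surviving contrasts, ...)."""
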