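"""Exception hierarchy for the pipeline.

Every boundary violation raises a subclass of :class:`PhylospreadError`
so callers (and the CLI) can distinguish user-input problems from bugs.
"""


class PhylospreadError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PhylospreadError):
    """Malformed input file or record (bad characters, duplicates, negatives)."""


class AlignmentError(FormatError):
    """Sequences that should be aligned have unequal lengths."""


class CrossReferenceError(PhylospreadError):
    """An identifier refers to an object that does not exist."""


class ConsistencyError(PhylospreadError):
    """Two inputs that must agree do not (e.g. pooling across regions)."""


class DegenerateDataError(PhylospreadError):
    """An operation's input is too small or too uniform to be meaningful."""


class ParameterError(PhylospreadError):
    """A parameter combination is invalid (e.g. mutation sites exhausted)."""
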