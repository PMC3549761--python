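"""Exception hierarchy shared across the package."""


class RrsnpError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RrsnpError):
    """A config object violates its invariants; message names the field."""


class FormatError(RrsnpError):
    """A record in an input file cannot be interpreted."""


class PreconditionError(RrsnpError):
    """An operation was called outside its documented precondition."""


class MissingDistanceError(RrsnpError):
    """A pair of individuals shares no jointly-typed loci."""


class DegenerateInputError(RrsnpError):
    """An ordination input has no positive eigenvalues."""


class PipelineError(RrsnpError):
    """A pipeline stage failed; message names the stage and record."""
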