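"""Exception hierarchy shared by all hybridkit modules."""


class HybridkitError(Exception):
    """Base class for all errors raised by hybridkit."""


class InputError(HybridkitError):
    """Invalid argument values or malformed in-memory inputs."""


class ParseError(HybridkitError):
    """A file could not be parsed into a valid domain object."""


class ValidationError(HybridkitError):
    """A domain object violates one of its invariants."""


class AnalysisError(HybridkitError):
    """An analysis step cannot proceed on otherwise valid data."""
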