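"""Exception hierarchy for paravec."""


class ParavecError(Exception):
    """Base class for all paravec errors."""


class ValidationError(ParavecError, ValueError):
    """An input violates a documented precondition or invariant."""


class FormatError(ParavecError, ValueError):
    """A file could not be parsed in the expected format."""


class MissingSpeciesError(ParavecError, KeyError):
    """A species was requested that is absent from a tree or centroid set."""


class UndefinedAngleError(ParavecError, ValueError):
    """An angle was requested for a zero-length vector."""


class NoSamplesError(ParavecError, ValueError):
    """Filtering removed every sample."""
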