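"""Exception hierarchy shared across the package."""


class MircleftError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MircleftError):
    """A file could not be parsed (bad header, malformed row)."""


class ValidationError(MircleftError):
    """An input value violates a documented precondition."""


class DomainError(MircleftError):
    """Inputs are structurally valid but mathematically inconsistent."""


class AliasConflictError(ValidationError):
    """Two records assign the same alias to different primary symbols."""
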