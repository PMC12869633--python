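"""Exception types shared across the package."""


class NmAtlasError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(NmAtlasError, ValueError):
    """A parameter block violates its own invariants."""


class MalformedInputError(NmAtlasError, ValueError):
    """An input record or file cannot be interpreted."""


class PlacementError(NmAtlasError, ValueError):
    """A guide or site cannot be placed with the requested geometry."""


class UndefinedPositionError(NmAtlasError, ValueError):
    """A per-position statistic was requested where it is not defined."""


class InvalidDesignError(NmAtlasError, ValueError):
    """A sample design does not match the comparison being requested."""
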