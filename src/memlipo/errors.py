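"""Exception hierarchy shared by all memlipo modules."""


class MemlipoError(Exception):
    """Base class for all memlipo errors."""


class ParameterError(MemlipoError, ValueError):
    """An argument is outside its documented domain."""


class DataError(MemlipoError, ValueError):
    """Input data are missing, malformed, or non-finite."""


class StateError(MemlipoError, RuntimeError):
    """An operation was applied to an object in the wrong processing state."""


class GeometryError(MemlipoError, ValueError):
    """Degenerate geometry (collinear atoms, empty structure, ...)."""


class ConfigurationError(MemlipoError, ValueError):
    """Inconsistent run configuration (e.g. a filter on an absent column)."""
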