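"""Exception hierarchy shared across the package."""


class NanocoronaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NanocoronaError, ValueError):
    """A scene or run configuration is invalid or infeasible."""


class IngestError(NanocoronaError, ValueError):
    """A localization file violates the declared dialect or contract."""


class InputError(NanocoronaError, ValueError):
    """An in-memory input violates an operation's precondition."""


class GeometryError(NanocoronaError, ValueError):
    """A point set is too degenerate to triangulate (collinear/coplanar)."""
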