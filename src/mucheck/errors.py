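"""Exception hierarchy shared across the package."""


class MucheckError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MucheckError):
    """Malformed input data (bad file, inconsistent table, schema violation)."""


class GeometryError(MucheckError):
    """Degenerate or misconfigured geometry (empty mask, ray misses grid...)."""


class InfeasibleError(MucheckError):
    """A requested plan/model configuration cannot be realized."""


class ScopeError(MucheckError):
    """The request falls outside the method's validity (e.g. multifield-optimized beams)."""
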