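"""Exception types used across the package."""


class FM2DError(Exception):
    """Base class for all package errors."""


class ConfigError(FM2DError):
    """Invalid configuration (exit code 2 in the CLI)."""


class SolverError(FM2DError):
    """Linear solver failure (exit code 3 in the CLI)."""


class GeometryError(FM2DError):
    """Geometric failure: self-intersection, vertex leaving the domain,
    degenerate incidence between interface and bulk mesh (exit code 4)."""
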