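"""Exception types shared across axokit modules."""


class AxokitError(Exception):
    """Base class for all axokit errors."""


class ValidationError(AxokitError, ValueError):
    """Invalid domain object or operation precondition."""


class DegenerateGeometryError(AxokitError, ValueError):
    """Geometry too degenerate to process (e.g. collinear lattice centers)."""


class ParseError(AxokitError, ValueError):
    """Malformed input file."""


class ConfigError(AxokitError, ValueError):
    """Invalid run configuration."""
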