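"""Exception hierarchy shared across the package."""


class SeedregnetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SeedregnetError, ValueError):
    """Input data violates a structural invariant (duplicate ids, negative counts...)."""


class ParseError(SeedregnetError, ValueError):
    """A file does not conform to its declared format."""


class ParameterError(SeedregnetError, ValueError):
    """A user-supplied parameter is outside its legal range."""


class DesignError(SeedregnetError, ValueError):
    """A sample design is inconsistent with the requested operation."""


class SizingError(SeedregnetError, ValueError):
    """Generated objects do not fit the configured capacity (e.g. contig too short)."""


class DegenerateInputError(SeedregnetError, ValueError):
    """Numerically degenerate input (e.g. constant vector in a correlation test)."""
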