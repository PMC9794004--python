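"""Exception hierarchy shared across the toolkit."""


class DualomicsError(Exception):
    """Base class for all package errors."""


class FormatError(DualomicsError):
    """Malformed input file (header, shape, or dialect problems)."""


class ValidationError(DualomicsError):
    """Data violates an invariant (negative abundance, duplicate ids, ...)."""


class ParameterError(DualomicsError):
    """A caller-supplied parameter is out of its admissible range."""


class ConfigError(DualomicsError):
    """A simulation or pipeline configuration is infeasible."""
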