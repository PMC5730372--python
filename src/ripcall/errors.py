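"""Exception hierarchy shared across the pipeline.

Validation errors mean the data violate an invariant; configuration errors
mean the run was set up wrong (missing column, bad path); parameter errors
mean a numeric argument is out of its documented range.
"""


class RipcallError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RipcallError):
    """A column mapping, path or config entry is missing or malformed."""


class ValidationError(RipcallError):
    """Input data violate a documented invariant (e.g. negative FPKM)."""


class ParameterError(RipcallError, ValueError):
    """A numeric parameter is outside its documented range."""
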