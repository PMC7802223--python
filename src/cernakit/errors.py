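"""Exception hierarchy shared across the package."""


class CernakitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CernakitError, ValueError):
    """A configuration object violates its invariants; message names the field."""


class InputError(CernakitError, ValueError):
    """Inputs to an operation are inconsistent or out of contract."""


class FormatError(InputError):
    """A file on disk does not parse as the expected format."""


class DegenerateInputError(InputError):
    """Numerically degenerate input (e.g. a zero column total)."""


class DesignError(InputError):
    """The sample design cannot support the requested procedure."""


class ConstantVectorError(CernakitError, ValueError):
    """Correlation requested on a zero-variance vector."""
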