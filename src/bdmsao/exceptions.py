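"""Exception hierarchy shared across the package."""


class BdmsaoError(Exception):
    """Base class for all package-specific errors."""


class InputError(BdmsaoError, ValueError):
    """A data file or in-memory table violates the input contract
    (missing cells, non-numeric values, ragged shapes)."""


class ConfigError(BdmsaoError, ValueError):
    """A parameter object or option combination is invalid
    (bad bounds, fold count larger than the sample count, ...)."""


class NumericError(BdmsaoError, ValueError):
    """A numeric precondition failed (non-finite positions and the like)."""
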