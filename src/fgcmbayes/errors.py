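"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An invalid configuration value; the message names the violated invariant."""


class SchemaError(ValueError):
    """An input table is missing a required column or has an unusable header."""


class ValidationError(ValueError):
    """Row-level validation failed; the message lists offending row numbers."""


class CollinearityError(ValueError):
    """The combined design matrix is numerically singular; names offending columns."""
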