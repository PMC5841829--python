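"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid configuration (bad parameter values, schema violations)."""


class NumericError(RuntimeError):
    """Numerical failure during a solver step (non-finite values, zero pivots)."""
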