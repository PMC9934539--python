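"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A configuration value is invalid or internally inconsistent."""


class ValidationError(ValueError):
    """An input violates an operation's preconditions."""


class SamplingError(RuntimeError):
    """A random sampling step cannot be satisfied (e.g. population too small)."""
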