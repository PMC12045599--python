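"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised when a simulation or analysis configuration is invalid."""


class StageError(RuntimeError):
    """Raised when a pipeline stage cannot run (missing inputs, bad stage name)."""
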