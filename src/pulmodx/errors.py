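"""Shared exception types."""


class LeakageError(RuntimeError):
    """A subject's data (or an augmented derivative of it) crossed a
    train/test boundary. Always a hard failure, never a warning."""


class ConfigError(ValueError):
    """A run configuration is malformed or references missing files."""
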