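"""Package-wide exception hierarchy."""


class BepanelError(Exception):
    """Base class for all bepanel errors."""


class ConfigError(BepanelError):
    """Invalid configuration or parameter values."""


class DataError(BepanelError):
    """Malformed, inconsistent or insufficient input data."""
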