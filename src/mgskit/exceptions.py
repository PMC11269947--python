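"""Package-wide exception types."""


class MgskitError(Exception):
    """Base class for all mgskit errors."""


class ConfigError(MgskitError, ValueError):
    """Invalid configuration (group sizes, thresholds, distribution parameters)."""


class InputError(MgskitError, ValueError):
    """Malformed input data (missing fields, negative counts, duplicates)."""
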