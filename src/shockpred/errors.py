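"""Exception hierarchy shared across the pipeline."""


class ShockpredError(Exception):
    """Base class for all package errors."""


class ConfigError(ShockpredError):
    """Invalid configuration (bad parameter, malformed matrix spec, ...)."""


class ParseError(ShockpredError):
    """Malformed input record; message carries row context."""


class ImputationError(ShockpredError):
    """An imputation engine cannot complete (e.g. all-missing column)."""
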