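"""Exception hierarchy shared across the package."""


class PrevsimError(Exception):
    """Base class for all package-specific errors."""


class CalibrationError(PrevsimError):
    """A scenario calibration has no solution (e.g. inconsistent tail efficacies)."""


class ConfigurationError(PrevsimError):
    """A design/scenario/engine combination is invalid (e.g. an empty arm)."""


class SchemaError(PrevsimError):
    """A run configuration failed validation; message names the offending keys."""
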