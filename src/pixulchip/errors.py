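"""Exception hierarchy shared by all subpackages."""


class PixulChipError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(PixulChipError):
    """Input violates a documented precondition or invariant."""


class CalibrationError(PixulChipError):
    """Ladder band detection or migration-model fitting failed."""


class FormatError(PixulChipError):
    """A file does not conform to its declared tabular/interval format."""


class ConfigurationError(PixulChipError):
    """Inconsistent run configuration (rules, layouts, simulator settings)."""
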