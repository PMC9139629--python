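"""Exception hierarchy shared across the package."""


class SmriskError(Exception):
    """Base class for all package-specific errors."""


class DVHFormatError(SmriskError):
    """A DVH table file could not be parsed (bad columns, non-monotone dose...)."""


class ValidationError(SmriskError, ValueError):
    """Parsed data violates a model precondition (negative volume, empty table...)."""


class OrganLookupError(SmriskError, KeyError):
    """An organ is missing from a parameter registry."""


class PairingError(SmriskError):
    """A cohort is incomplete: some patient lacks a modality or organ cell."""


class ConfigurationError(SmriskError):
    """A profile registry or run manifest is invalid or incomplete."""
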