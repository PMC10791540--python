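"""Exception hierarchy used across the package."""


class CTRecurError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CTRecurError, ValueError):
    """A spec/config object violates its invariants."""


class InputError(CTRecurError, ValueError):
    """Input data violate an operation's preconditions."""


class VolumeFormatError(CTRecurError, ValueError):
    """A volume file is readable but structurally invalid (e.g. mixed slice shapes)."""


class VolumeIOError(CTRecurError, IOError):
    """A volume file is missing or unreadable."""
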