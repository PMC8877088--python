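"""Exception hierarchy for the VEA package."""


class VeaError(ValueError):
    """Base class for all VEA-specific errors."""


class ConfigError(VeaError):
    """Invalid configuration: missing columns, bad parameters, absent files."""


class FileFormatError(VeaError):
    """An input file violates its declared format contract."""
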