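"""Exception hierarchy.

Two broad families matter for the CLI exit-code contract: configuration
problems (exit 2) and data/geometry problems (exit 3).
"""


class PetRangeError(Exception):
    """Base class for all package errors."""


class ConfigError(PetRangeError):
    """Invalid or inconsistent configuration (CLI exit code 2)."""


class DataError(PetRangeError):
    """Invalid data or file content (CLI exit code 3)."""


class GeometryError(DataError):
    """Phantom geometry does not fit the requested grid."""


class FormatError(DataError):
    """A file could not be parsed as the expected format."""


class KernelCalibrationError(ConfigError):
    """The range kernel has no median-range calibration target."""


class ProfileTruncatedError(DataError):
    """A line profile ends before the requested level is crossed."""
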