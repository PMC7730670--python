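"""Exception hierarchy shared across the pipeline stages."""


class HsiError(Exception):
    """Base class for all package-specific errors."""


class MetadataError(HsiError):
    """Required metadata (e.g. the wavelength list of an ENVI header) is missing."""


class FormatError(HsiError):
    """On-disk data does not match its declared layout."""


class ValidationError(HsiError, ValueError):
    """An in-memory object violates its contract."""


class RangeError(HsiError, ValueError):
    """A wavelength or interval falls outside the supported range."""


class CalibrationError(HsiError):
    """White/dark references are unusable at one or more positions."""


class SizeError(HsiError, ValueError):
    """A requested size exceeds what the input can provide."""


class AlignmentError(HsiError):
    """Spatially companion objects (cube vs. label map) disagree in shape."""


class ArchitectureError(HsiError):
    """A network layer cannot be applied to the extent left by earlier layers."""


class StateError(HsiError):
    """An operation was called before its prerequisite state was established."""


class ConfigError(HsiError, ValueError):
    """A run or cohort configuration is inconsistent."""
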