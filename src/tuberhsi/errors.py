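"""Exception hierarchy shared across the package."""


class TuberHSIError(Exception):
    """Base class for all package-specific errors."""


class InvalidAxisError(TuberHSIError, ValueError):
    """Wavelength axis cannot be constructed (bad span or band count)."""


class FormatError(TuberHSIError, ValueError):
    """Malformed or inconsistent ENVI header/raster pair."""


class DegenerateReferenceError(TuberHSIError, ValueError):
    """White minus dark reference is below tolerance somewhere."""


class EmptySelectionError(TuberHSIError, ValueError):
    """A mask or selection contains no foreground pixels."""


class EmptyMaskError(EmptySelectionError):
    """Morphological cleaning removed every foreground pixel."""


class DegenerateImageError(TuberHSIError, ValueError):
    """Image is constant; no threshold separates two classes."""


class DegenerateSpectrumError(TuberHSIError, ValueError):
    """A spectrum is flat (SNV) or uncorrectable (MSC slope ~ 0)."""


class DegenerateLabelsError(TuberHSIError, ValueError):
    """Fewer than two classes present where a binary problem is required."""


class ParameterError(TuberHSIError, ValueError):
    """An operator parameter is out of its valid range."""


class ConfigError(TuberHSIError, ValueError):
    """Pipeline configuration is invalid (unknown chain step, bad mode...)."""
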