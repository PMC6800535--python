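"""Exception hierarchy shared across the package."""


class AdcDarError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AdcDarError, ValueError):
    """A required configuration field is missing or inconsistent."""


class UnknownLinkerError(AdcDarError, KeyError):
    """Requested linker name is not in the registry."""


class DegenerateDesignError(AdcDarError, ValueError):
    """Regression design matrix is singular (e.g. one distinct concentration)."""


class SpectrumRangeError(AdcDarError, ValueError):
    """Queried wavelength or m/z lies outside the recorded span."""


class SingularRatioError(AdcDarError, ZeroDivisionError):
    """UV ratio sits on the pole of the DAR inversion formula."""


class NoPeakError(AdcDarError, ValueError):
    """Spectrum carries no usable peak (e.g. all-zero intensities)."""


class SpectrumParseError(AdcDarError, ValueError):
    """Malformed spectrum file; carries the offending line number when known."""


class MapComparisonError(AdcDarError, ValueError):
    """Digest maps being compared do not share a parent sequence."""
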