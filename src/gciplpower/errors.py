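"""Exception hierarchy for gciplpower."""


class GciplPowerError(Exception):
    """Base class for all package-specific errors."""


class CohortParseError(GciplPowerError):
    """A cohort CSV cell could not be parsed (carries the offending row number)."""


class CohortValidationError(GciplPowerError):
    """A cohort record is structurally invalid (missing timepoint/metric, bad laterality...)."""


class InsufficientDataError(GciplPowerError):
    """Fewer records than the operation requires (e.g. n < 2 for a sample SD)."""


class InvalidEffectError(GciplPowerError):
    """Effect size outside (0, 1]; a zero effect makes the sample size undefined."""


class InvalidDispersionError(GciplPowerError):
    """Non-positive standard deviation passed to a power or sample-size formula."""


class InfiniteSampleSizeError(GciplPowerError):
    """Zero mean difference: no finite sample size detects a null effect."""
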