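"""Exception hierarchy shared across the package."""


class HeatwaveKitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HeatwaveKitError):
    """A file is missing required variables/columns or is malformed."""


class ResolutionError(HeatwaveKitError):
    """The time axis is not a daily calendar within contiguous blocks."""


class DomainError(HeatwaveKitError):
    """A requested location falls outside the grid bounding box."""


class ValidationError(HeatwaveKitError):
    """A table row or configuration value fails validation."""


class InsufficientBaselineError(HeatwaveKitError):
    """The series does not overlap the requested baseline window."""
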