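"""Exception hierarchy for measurement-level failure modes."""


class OculopulseError(Exception):
    """Base class for all package-specific errors."""


class InsufficientBeatsError(OculopulseError):
    """Fewer than two systolic peaks were found in a pulse trace."""


class PhaseUndefinedError(OculopulseError):
    """The requested time lies outside the span where cardiac phase is defined."""


class NoApplanationError(OculopulseError):
    """The central cornea never flattens below the applanation threshold."""


class NoVibrationError(OculopulseError):
    """No spectral peak above the low-cut frequency exceeds the noise floor."""


class ContourRejectedError(OculopulseError):
    """A frame has too few valid edge columns to complete the contour."""


class UndefinedCorrelationError(OculopulseError):
    """Pearson correlation is undefined (constant vector, zero denominator)."""


class EmptyRetainedSetError(OculopulseError):
    """Outlier rejection removed every subject."""


class ManifestError(OculopulseError):
    """A measurement manifest is malformed."""


class RenderGeometryError(OculopulseError):
    """Requested synthetic geometry would push the contour outside the frame."""
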