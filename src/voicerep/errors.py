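"""Exception hierarchy shared across the package."""


class VoicerepError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(VoicerepError, ValueError):
    """A caller-supplied argument violates a documented precondition."""


class IncompatibleSpaceError(VoicerepError):
    """Two volumetric objects do not share grid shape and affine."""


class ROIShortfallError(VoicerepError):
    """Fewer voxels pass the selection threshold than the requested ROI size.

    Carries ``achievable``, the number of supra-threshold voxels available,
    so callers can decide whether to relax the threshold or shrink the ROI.
    """

    def __init__(self, requested: int, achievable: int, message: str | None = None):
        self.requested = requested
        self.achievable = achievable
        super().__init__(
            message
            or f"ROI of {requested} voxels requested but only "
            f"{achievable} voxels pass the threshold"
        )


class PeakNotFoundError(VoicerepError):
    """No supra-threshold local maximum exists for a reference coordinate."""


class UndefinedPeakError(VoicerepError):
    """A modulation spectrum has no usable peak (e.g. all-zero grid)."""


class UndefinedCorrelationError(VoicerepError):
    """Rank correlation is undefined because one input has zero rank variance."""


class DegenerateComparisonError(VoicerepError):
    """A paired test is degenerate (e.g. all paired differences are zero)."""
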