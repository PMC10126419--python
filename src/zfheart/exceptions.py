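"""Exception hierarchy for zfheart.

All recoverable analysis failures derive from :class:`ZfHeartError` so the CLI
can log a per-fish failure and continue with the next recording.
"""


class ZfHeartError(Exception):
    """Base class for all zfheart errors."""


class FormatError(ZfHeartError):
    """An input file could not be read, or frames disagree in size/dtype."""


class InsufficientDataError(ZfHeartError):
    """Too few frames/samples for the requested computation."""


class NoHeartDetectedError(ZfHeartError):
    """No supra-threshold pixels when locating the heart ROI."""


class SegmentationFailureError(ZfHeartError):
    """A chamber seed matched no supra-threshold component in most frames."""

    def __init__(self, chamber: str, miss_fraction: float):
        self.chamber = chamber
        self.miss_fraction = miss_fraction
        super().__init__(
            f"segmentation failed for chamber '{chamber}': no supra-threshold "
            f"component overlapped its seed in {miss_fraction:.0%} of frames"
        )


class NoMotionError(ZfHeartError):
    """Brightfield video shows no temporal intensity variation."""


class EmptySignalError(ZfHeartError):
    """A chamber mask is empty in every frame; no trace can be extracted."""
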