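"""Shared vocabulary for the lower cervical spine.

Only C4-C7 are analyzed; the upper cervical spine (C0-C3) is out of scope.
Angles are in degrees, extension positive, and each motion segment's angle is
the rotation of its upper vertebra relative to its lower one.
"""

#: Vertebrae tracked, cranial to caudal.
VERTEBRAE: tuple[str, ...] = ("C4", "C5", "C6", "C7")

#: Motion segments (upper-lower vertebra pairs), cranial to caudal.
SEGMENTS: tuple[str, ...] = ("C4-C5", "C5-C6", "C6-C7")

#: Map segment label -> (upper vertebra, lower vertebra).
SEGMENT_PAIRS: dict[str, tuple[str, str]] = {
    "C4-C5": ("C4", "C5"),
    "C5-C6": ("C5", "C6"),
    "C6-C7": ("C6", "C7"),
}


class CervikinError(Exception):
    """Base class for package-specific errors."""


class PeakOverlapError(CervikinError):
    """Requested contribution peaks are closer than the frame grid can resolve."""


class FrameOutOfViewError(CervikinError):
    """A vertebral body leaves the rendered field of view."""

    def __init__(self, frame: int, vertebra: str):
        self.frame = frame
        self.vertebra = vertebra
        super().__init__(f"vertebra {vertebra} leaves the field of view at frame {frame}")


class InsufficientMotionError(CervikinError):
    """Net block rotation is below the analyzable minimum."""


class ZeroVarianceError(CervikinError):
    """A statistic is undefined because the input has no variance."""
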