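"""Exception hierarchy shared by the pipelines."""


class HepmorphError(Exception):
    """Base class for all package-specific errors."""


class OutlineParseError(HepmorphError):
    """An outline text file contains a token that is not a number."""


class MalformedOutlineError(HepmorphError):
    """An outline has fewer than 3 distinct vertices or zero signed area."""


class GeometryError(HepmorphError):
    """Invalid polygon geometry (self-intersection, clipped window...)."""


class GridError(HepmorphError):
    """Shape does not fit in the raster window, or grid parameters invalid."""


class IncompatibleDescriptorsError(HepmorphError):
    """Two descriptors were computed on different (D, T, R) grids."""


class InsufficientFramesError(HepmorphError):
    """A temporal operation needs more frames than were supplied."""


class DegenerateHistogramError(HepmorphError):
    """Automatic thresholding on a (near-)constant volume."""


class StageError(HepmorphError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


class VolumeFormatError(HepmorphError):
    """A TIFF stack is corrupt or does not match the declared layout."""
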