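"""Exception hierarchy for rootone."""


class RootOneError(Exception):
    """Base class for all rootone errors."""


class VolumeError(RootOneError):
    """Invalid volume data, calibration, or file container."""


class PeakNotFoundError(RootOneError):
    """No localised histogram peak inside the search window."""


class StitchError(RootOneError):
    """No plausible slice overlap between two scans."""


class DegenerateDistributionError(RootOneError):
    """Automatic thresholding asked of a constant distribution."""


class SeedError(RootOneError):
    """Seed voxel does not sit on foreground.

    Carries the nearest foreground voxel (z, y, x) as a suggestion when one
    exists.
    """

    def __init__(self, message, nearest_foreground=None):
        super().__init__(message)
        self.nearest_foreground = nearest_foreground


class GeometryError(RootOneError):
    """Phantom geometry outside the soil column or otherwise invalid."""
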