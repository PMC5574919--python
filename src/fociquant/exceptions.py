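"""Package exceptions."""


class FociquantError(Exception):
    """Base class for fociquant errors."""


class DimensionError(FociquantError):
    """Channel grids (or foci images) that must share dimensions do not."""


class FormatError(FociquantError):
    """Input file is not a grayscale image of a supported bit depth."""


class DegenerateImageError(FociquantError):
    """Image histogram has a single level; thresholding is undefined."""


class ClusterDegeneracyError(FociquantError):
    """Fewer distinct intensity values than requested clusters."""


class PlacementError(FociquantError):
    """Could not place the requested number of nuclei without overlap."""


class ConfigError(FociquantError):
    """Invalid run configuration or manifest."""
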