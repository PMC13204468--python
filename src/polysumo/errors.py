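"""Exception and warning types shared across the pipeline."""


class PolysumoError(Exception):
    """Base class for all pipeline errors."""


class ChannelShapeMismatch(PolysumoError):
    """Channels of one field do not share a spatial shape."""


class UnsupportedTiffDialect(PolysumoError):
    """TIFF sample format the reader does not handle."""


class NotALabelImage(PolysumoError):
    """A label TIFF holds non-integral values."""


class DegenerateHistogram(PolysumoError):
    """Histogram with a single occupied bin; no threshold exists."""


class ParentLinkageBroken(PolysumoError):
    """Cell / cytoplasm labels are not a subset of the nuclei labels."""


class PlacementFailed(PolysumoError):
    """Scene generator could not place the requested objects."""


class DegenerateDynamicRange(UserWarning):
    """Raised (as a warning) when rescaling a constant image."""
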